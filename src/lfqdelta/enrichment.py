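"""Gene-set over/under-representation analysis over flat gene sets.

For a query of n genes drawn from a universe of N, a term with K
members inside the universe and an observed overlap of k, significance
is the two-sided hypergeometric probability — the doubled smaller tail,
capped at 1.  Terms must overlap the query by at least ``min_genes``
genes and cover at least ``min_coverage`` of their members to enter the
Bonferroni step-down (Holm) adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneSetCollection
from .diffstats import holm_adjust

__all__ = [
    "EnrichmentResult",
    "hypergeometric_two_sided_p",
    "enrich_query",
]


def hypergeometric_two_sided_p(N: int, K: int, n: int, k):
    """Two-sided hypergeometric p: min(1, 2*min(P[X >= k], P[X <= k])).

    ``X ~ Hypergeometric(N, K, n)`` — overlap of a uniformly random
    n-subset of an N-universe with a fixed K-subset.  Doubling the
    smaller tail and capping at 1 is the simple conservative two-sided
    convention for a discrete statistic.  ``k`` may be a scalar or an
    array of overlaps (scalar in, float out).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid parameters N={N}, K={K}, n={n}")
    lo, hi = max(0, n + K - N), min(n, K)
    k_arr = np.asarray(k)
    if np.any((k_arr < lo) | (k_arr > hi)):
        raise ValueError(f"overlap k={k} outside support [{lo}, {hi}]")
    upper = sps.hypergeom.sf(k_arr - 1, N, K, n)  # P[X >= k]
    lower = sps.hypergeom.cdf(k_arr, N, K, n)  # P[X <= k]
    p = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    return float(p) if np.isscalar(k) or k_arr.ndim == 0 else p


@dataclass
class EnrichmentResult:
    """Per-term enrichment statistics for one query."""

    term_id: str
    term_name: str
    term_size: int  # K, within the universe
    query_size: int  # n
    overlap: int  # k
    overlap_genes: tuple
    coverage: float  # k / K
    direction: str  # 'enriched' or 'depleted' vs expectation n*K/N
    p_value: float
    p_adjusted: float  # Holm, NaN when filters not passed
    passed_filters: bool

    def as_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_name": self.term_name,
            "term_size": self.term_size,
            "query_size": self.query_size,
            "overlap": self.overlap,
            "coverage": self.coverage,
            "direction": self.direction,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "passed_filters": self.passed_filters,
            "overlap_genes": ";".join(self.overlap_genes),
        }


def results_frame(results: "list[EnrichmentResult]") -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def enrich_query(
    query,
    genesets: GeneSetCollection,
    universe,
    min_genes: int = 2,
    min_coverage: float = 0.10,
    K_min: int | None = None,
    K_max: int | None = None,
) -> "list[EnrichmentResult]":
    """Test every term for over/under-representation in ``query``.

    Parameters
    ----------
    query
        Gene symbols of interest (e.g. the significantly modulated
        proteins); must be a subset of ``universe``.
    genesets
        Flat gene-set collection; members are intersected with the
        universe to obtain each term's effective size K.
    universe
        Background gene symbols (typically the quantified proteome).
    min_genes, min_coverage
        A term passes the filters iff its overlap k >= ``min_genes``
        and k/K >= ``min_coverage``.  Holm adjustment runs only across
        passing terms.
    K_min, K_max
        Optional term-size window applied to K before testing — a flat
        stand-in for ontology-level selection.

    Results are sorted by adjusted p, then raw p, then term id; terms
    failing the filters sort after passing ones.
    """
    universe_set = {g.strip().upper() for g in universe}
    query_set = {g.strip().upper() for g in query}
    outside = query_set - universe_set
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:10]}")
    if len(genesets) == 0:
        raise ValueError("empty gene-set collection")
    N = len(universe_set)
    n = len(query_set)

    results: list[EnrichmentResult] = []
    for term in genesets:
        members = [g for g in term.genes if g in universe_set]
        K = len(members)
        if K == 0:
            continue
        if K_min is not None and K < K_min:
            continue
        if K_max is not None and K > K_max:
            continue
        overlap_genes = tuple(sorted(g for g in members if g in query_set))
        k = len(overlap_genes)
        p = hypergeometric_two_sided_p(N, K, n, k)
        coverage = k / K
        expected = n * K / N
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.name,
                term_size=K,
                query_size=n,
                overlap=k,
                overlap_genes=overlap_genes,
                coverage=coverage,
                direction="enriched" if k > expected else "depleted",
                p_value=p,
                p_adjusted=np.nan,
                passed_filters=(k >= min_genes and coverage >= min_coverage),
            )
        )

    passing = [r for r in results if r.passed_filters]
    if passing:
        adjusted = holm_adjust([r.p_value for r in passing])
        for r, a in zip(passing, adjusted):
            r.p_adjusted = float(a)

    def sort_key(r: EnrichmentResult):
        adj = r.p_adjusted if r.passed_filters else np.inf
        return (not r.passed_filters, adj, r.p_value, r.term_id)

    return sorted(results, key=sort_key)
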