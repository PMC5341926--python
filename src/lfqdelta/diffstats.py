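"""Moderated test statistics with permutation-based FDR.

The pairwise statistic is the SAM-style moderated t

    d = (mean_B - mean_A) / (se + s0)

where ``se`` is the classical pooled-variance standard error and ``s0``
a small positive constant that damps the significance of tiny fold
changes with tiny variance.  Significance is calibrated by sample-label
permutation: for a threshold t the false discovery rate is estimated as

    FDR(t) = min(1, mean_perm #{j : |d_j^perm| >= t} / #{j : |d_j^obs| >= t})

with candidate thresholds at the observed |d| values, and each protein's
q-value is the best (smallest) FDR of any rejection set containing it,
monotonized so q never decreases as |d| decreases.  No pi0 multiplier is
applied.  Permutations are column-wise: one label reassignment is shared
by all proteins, preserving the between-protein correlation structure.

The permutation null set excludes relabelings equivalent to the
observed assignment — the identity, the two-group mirror (which yields
identical |d|), and for the multi-group test any labeling inducing the
observed partition of samples.  Including them would add the observed
rejections themselves to the numerator of every FDR estimate (a floor
of 2/20 = 0.1 in a 3-vs-3 design), leaving the test powerless at a 5%
FDR in exactly the small balanced designs it exists for.


The multi-group analogue moderates the one-way F statistic as
``F' = MS_between / (sqrt(MS_within) + s0_anova)^2`` (classical F at
``s0_anova = 0``) and permutes all sample labels jointly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, factorial, prod

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import QuantMatrix, SampleDesign, Stage

__all__ = [
    "ContrastResult",
    "AnovaResult",
    "moderated_t",
    "moderated_f",
    "permutation_fdr",
    "two_sample_contrast",
    "multi_group_anova",
    "holm_adjust",
    "volcano_boundary",
    "ddct_fold_change",
]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def moderated_t(values_a, values_b, s0: float = 0.5):
    """Moderated two-sample statistic d = (mean_B - mean_A)/(se + s0).

    Parameters
    ----------
    values_a, values_b
        Samples for the two groups.  Either 1-D (one protein) or 2-D
        arrays of shape ``(n_proteins, n_replicates)``.
    s0
        Non-negative moderation constant.

    Returns
    -------
    (delta, se, d, p)
        Log2 fold change ``mean_B - mean_A``, pooled standard error, the
        moderated statistic, and the two-sided parametric p-value of the
        classical ``t = delta/se`` at ``n_A + n_B - 2`` degrees of
        freedom.  ``p = 1`` where ``se = 0`` and ``delta = 0``; ``p = 0``
        where ``se = 0`` and ``delta != 0``.  Scalars in, scalars out.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    scalar = np.ndim(values_a) == 1
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >=2 values per side")
    delta = B.mean(axis=1) - A.mean(axis=1)
    sp2 = ((n_a - 1) * A.var(axis=1, ddof=1) + (n_b - 1) * B.var(axis=1, ddof=1)) / (
        n_a + n_b - 2
    )
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    denom = se + s0
    if s0 == 0 and np.any((se == 0) & (delta != 0)):
        raise ValueError("se = 0 with s0 = 0 and a nonzero fold change: d undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, delta / np.where(denom > 0, denom, 1.0), 0.0)
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), np.inf * np.sign(delta))
    t = np.where((se == 0) & (delta == 0), 0.0, t)
    df = n_a + n_b - 2
    p = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    p = np.where((se == 0) & (delta == 0), 1.0, p)
    if scalar:
        return delta[0], se[0], d[0], p[0]
    return delta, se, d, p


def moderated_f(groups: "list[np.ndarray]", s0_anova: float = 0.0):
    """Moderated one-way statistic F' = MS_between/(sqrt(MS_within)+s0)^2.

    ``groups`` is a list of 1-D or 2-D arrays (proteins × replicates).
    Returns ``(f_mod, f_classical, p)`` with the parametric p from the
    classical F at ``(k-1, N-k)`` degrees of freedom.
    """
    if s0_anova < 0:
        raise ValueError("s0_anova must be >= 0")
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    scalar = np.ndim(groups[0]) == 1
    k = len(mats)
    if k < 2:
        raise ValueError("need >=2 groups")
    sizes = [m.shape[1] for m in mats]
    if any(n < 2 for n in sizes):
        raise ValueError("every group needs >=2 samples")
    N = sum(sizes)
    means = np.stack([m.mean(axis=1) for m in mats])  # (k, m)
    grand = sum(n * mu for n, mu in zip(sizes, means)) / N
    ss_between = sum(n * (mu - grand) ** 2 for n, mu in zip(sizes, means))
    ss_within = sum(
        (n - 1) * m.var(axis=1, ddof=1) for n, m in zip(sizes, mats)
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_classical = np.where(ms_within > 0, ms_between / np.where(ms_within > 0, ms_within, 1.0), np.inf)
        denom = np.sqrt(ms_within) + s0_anova
        f_mod = np.where(denom > 0, ms_between / np.where(denom > 0, denom, 1.0) ** 2, np.inf)
    f_classical = np.where((ms_within == 0) & (ms_between == 0), 0.0, f_classical)
    f_mod = np.where((denom == 0) & (ms_between == 0), 0.0, f_mod)
    p = np.where(
        np.isinf(f_classical),
        0.0,
        sps.f.sf(np.where(np.isinf(f_classical), 0, f_classical), k - 1, N - k),
    )
    if scalar:
        return f_mod[0], f_classical[0], p[0]
    return f_mod, f_classical, p


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def permutation_fdr(observed_stats, permuted_stats, q_star: float = 0.05):
    """SAM-style plug-in q-values from permutation exceedance counts.

    Parameters
    ----------
    observed_stats
        |d| per protein (length m).  Values are compared by magnitude;
        the absolute value is taken defensively.
    permuted_stats
        B × m matrix of |d| under label permutations.
    q_star
        Significance threshold used only to locate the cutoff ``c*``.

    Returns
    -------
    (q, c_star)
        q-value per protein (monotone non-decreasing as |d| decreases)
        and the smallest observed |d| with ``q <= q_star`` (``inf`` when
        no protein reaches significance).

    Ties in |d| share a candidate threshold and are counted together.
    """
    obs = np.abs(np.asarray(observed_stats, dtype=float))
    if obs.size == 0:
        raise ValueError("empty observed statistics")
    perm = np.abs(np.asarray(permuted_stats, dtype=float))
    perm = np.atleast_2d(perm)
    if perm.shape[1] != obs.size:
        raise ValueError(
            f"permuted stats have {perm.shape[1]} proteins, observed {obs.size}"
        )
    n_perm = perm.shape[0]

    # unique thresholds, descending; R(t) counts ties together
    thresholds, inverse, counts = np.unique(-obs, return_inverse=True, return_counts=True)
    thresholds = -thresholds  # descending
    R = np.cumsum(counts)  # obs >= threshold_u

    perm_sorted = np.sort(perm, axis=None)
    total = perm_sorted.size
    exceed = total - np.searchsorted(perm_sorted, thresholds, side="left")
    V_bar = exceed / n_perm
    fdr = np.minimum(1.0, V_bar / R)

    # q_u = min FDR over thresholds <= t_u (suffix minimum) — monotonization
    q_u = np.minimum.accumulate(fdr[::-1])[::-1]
    q = q_u[inverse]

    sig = np.flatnonzero(q_u <= q_star)
    c_star = thresholds[sig[-1]] if sig.size else np.inf
    return q, c_star


def _distinct_two_group_assignments(n: int, n_a: int, exclude_observed: bool = True):
    """Distinct splits of ``range(n)`` into sizes (n_a, n - n_a).

    The observed split (first ``n_a`` indices) and, in balanced designs,
    its mirror are dropped when ``exclude_observed`` — they carry the
    observed |d| values, not null draws.
    """
    idx = np.arange(n)
    observed = frozenset(range(n_a))
    mirror = frozenset(range(n_a, n)) if 2 * n_a == n else None
    for combo in itertools.combinations(range(n), n_a):
        if exclude_observed and frozenset(combo) in (observed, mirror):
            continue
        a = np.asarray(combo, dtype=int)
        b = np.setdiff1d(idx, a, assume_unique=True)
        yield a, b


@dataclass
class ContrastResult:
    """Per-protein results of one moderated two-sample comparison."""

    protein_ids: list[str]
    gene_symbols: list[str]
    group_a: str
    group_b: str
    log2_fc: np.ndarray
    se: np.ndarray
    d_stat: np.ndarray
    p_parametric: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray
    s0: float
    n_permutations: int
    q_star: float
    cutoff: float
    seed: int | None
    permutation_scheme: str = "monte-carlo"
    df: int = 0

    @property
    def label(self) -> str:
        return f"{self.group_b}_vs_{self.group_a}"

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "gene": self.gene_symbols,
                "log2_fc": self.log2_fc,
                "se": self.se,
                "d_stat": self.d_stat,
                "p_parametric": self.p_parametric,
                "q_value": self.q_value,
                "significant": self.significant,
            }
        )


@dataclass
class AnovaResult:
    """Per-protein results of the moderated multi-group test."""

    protein_ids: list[str]
    gene_symbols: list[str]
    groups: list[str]
    f_stat: np.ndarray
    p_parametric: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray
    s0_anova: float
    n_permutations: int
    q_star: float
    cutoff: float
    seed: int | None
    permutation_scheme: str = "monte-carlo"

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    @property
    def significant_ids(self) -> list[str]:
        return [p for p, s in zip(self.protein_ids, self.significant) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "gene": self.gene_symbols,
                "f_stat": self.f_stat,
                "p_parametric": self.p_parametric,
                "q_value": self.q_value,
                "significant": self.significant,
            }
        )


def two_sample_contrast(
    quant: QuantMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    s0: float = 0.5,
    n_permutations: int = 250,
    q_star: float = 0.05,
    seed: int | None = 0,
    scheme: str = "auto",
) -> ContrastResult:
    """Moderated t-test of ``group_b`` vs ``group_a`` with permutation FDR.

    Permutations reassign the pooled samples of the two groups into
    sizes ``(n_A, n_B)`` uniformly at random, one reassignment shared by
    all proteins.  When the number of distinct reassignments does not
    exceed ``n_permutations`` they are enumerated exhaustively instead
    (enumeration triggers at the C(6,3) = 20 splits of a 3-vs-3
    design); reassignments equivalent to the observed one are excluded
    in both modes.  ``scheme`` forces ``'exhaustive'`` or
    ``'monte-carlo'`` instead of the automatic choice.
    """
    quant.require_stage(Stage.IMPUTED)
    for g in (group_a, group_b):
        if g not in design.groups:
            raise ValueError(f"group {g!r} not in design")
        if len(design.samples_in(g)) < 2:
            raise ValueError(f"group {g!r} needs >=2 samples for permutation testing")
    cols_a = design.column_indices(quant, group_a)
    cols_b = design.column_indices(quant, group_b)
    X = quant.values
    delta, se, d, p = moderated_t(X[:, cols_a], X[:, cols_b], s0)

    pooled = np.concatenate([cols_a, cols_b])
    n_a, n_b = cols_a.size, cols_b.size
    n = n_a + n_b
    n_distinct = comb(n, n_a)
    if scheme == "auto":
        scheme = "exhaustive" if n_distinct <= n_permutations else "monte-carlo"
    if scheme == "exhaustive":
        splits = list(_distinct_two_group_assignments(n, n_a))
        idx_a = np.stack([pooled[a] for a, _ in splits])
        idx_b = np.stack([pooled[b] for _, b in splits])
    elif scheme == "monte-carlo":
        rng = np.random.default_rng(seed)
        observed = frozenset(range(n_a))
        mirror = frozenset(range(n_a, n)) if n_a == n_b else None
        rows = []
        while len(rows) < n_permutations:
            order = rng.permutation(n)
            if frozenset(order[:n_a].tolist()) in (observed, mirror):
                continue
            rows.append(order)
        orders = np.stack(rows)
        idx_a = pooled[orders[:, :n_a]]
        idx_b = pooled[orders[:, n_a:]]
    else:
        raise ValueError("scheme must be 'auto', 'exhaustive' or 'monte-carlo'")

    perm_d = _perm_moderated_t_abs(X, idx_a, idx_b, s0)
    q, c_star = permutation_fdr(np.abs(d), perm_d, q_star)
    return ContrastResult(
        protein_ids=quant.protein_ids,
        gene_symbols=quant.gene_symbols,
        group_a=group_a,
        group_b=group_b,
        log2_fc=delta,
        se=se,
        d_stat=d,
        p_parametric=p,
        q_value=q,
        significant=q <= q_star,
        s0=s0,
        n_permutations=idx_a.shape[0],
        q_star=q_star,
        cutoff=c_star,
        seed=seed,
        permutation_scheme=scheme,
        df=n_a + n_b - 2,
    )


def _perm_moderated_t_abs(X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float) -> np.ndarray:
    """|d| for every permutation: returns (B, m).

    ``idx_a``/``idx_b`` are (B, n_a)/(B, n_b) column-index matrices.
    Vectorized over permutations; memory is O(m · B · n).
    """
    n_a, n_b = idx_a.shape[1], idx_b.shape[1]
    A = X[:, idx_a]  # (m, B, n_a)
    B_ = X[:, idx_b]
    delta = B_.mean(axis=2) - A.mean(axis=2)
    sp2 = ((n_a - 1) * A.var(axis=2, ddof=1) + (n_b - 1) * B_.var(axis=2, ddof=1)) / (
        n_a + n_b - 2
    )
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, delta / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(d).T


def _distinct_multigroup_count(sizes: "list[int]") -> int:
    return factorial(sum(sizes)) // prod(factorial(n) for n in sizes)


def _observed_partition(sizes: "list[int]") -> frozenset:
    bounds = np.cumsum([0] + list(sizes))
    return frozenset(
        frozenset(range(bounds[g], bounds[g + 1])) for g in range(len(sizes))
    )


def _induced_partition(order, sizes: "list[int]") -> frozenset:
    bounds = np.cumsum([0] + list(sizes))
    return frozenset(
        frozenset(int(x) for x in order[bounds[g]:bounds[g + 1]])
        for g in range(len(sizes))
    )


def _distinct_multigroup_assignments(sizes: "list[int]", exclude_observed: bool = True):
    """Distinct assignments of range(N) into consecutive groups of ``sizes``.

    Assignments inducing the observed partition (the statistic is
    invariant to group relabeling) are dropped when ``exclude_observed``.
    """
    N = sum(sizes)
    observed = _observed_partition(sizes)

    def rec(remaining: tuple, sizes_left: "list[int]"):
        if not sizes_left:
            yield []
            return
        n = sizes_left[0]
        for combo in itertools.combinations(remaining, n):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    for parts in rec(tuple(range(N)), list(sizes)):
        order = np.concatenate([np.asarray(p, dtype=int) for p in parts])
        if exclude_observed and _induced_partition(order, sizes) == observed:
            continue
        yield order


def multi_group_anova(
    quant: QuantMatrix,
    design: SampleDesign,
    n_permutations: int = 250,
    q_star: float = 0.05,
    seed: int | None = 0,
    s0_anova: float = 0.0,
    scheme: str = "auto",
) -> AnovaResult:
    """Moderated one-way test across all design groups with permutation FDR.

    The statistic is ``F' = MS_between/(sqrt(MS_within)+s0_anova)^2``
    (classical F at the default ``s0_anova = 0``); permutations shuffle
    all sample labels jointly, enumerating all distinct group
    assignments when there are no more than ``n_permutations`` of them.
    Labelings that induce the observed partition of samples are
    excluded from the null set in both modes.
    """
    quant.require_stage(Stage.IMPUTED)
    if len(design.groups) < 2:
        raise ValueError("need >=2 groups")
    col_sets = [design.column_indices(quant, g) for g in design.groups]
    sizes = [c.size for c in col_sets]
    for g, n in zip(design.groups, sizes):
        if n < 2:
            raise ValueError(f"group {g!r} needs >=2 samples")
    X = quant.values
    f_mod, _, p = moderated_f([X[:, c] for c in col_sets], s0_anova)

    pooled = np.concatenate(col_sets)
    N = pooled.size
    n_distinct = _distinct_multigroup_count(sizes)
    if scheme == "auto":
        scheme = "exhaustive" if n_distinct <= n_permutations else "monte-carlo"
    if scheme == "exhaustive":
        orders = np.stack(list(_distinct_multigroup_assignments(sizes)))
    elif scheme == "monte-carlo":
        rng = np.random.default_rng(seed)
        observed = _observed_partition(sizes)
        rows = []
        while len(rows) < n_permutations:
            order = rng.permutation(N)
            if _induced_partition(order, sizes) == observed:
                continue
            rows.append(order)
        orders = np.stack(rows)
    else:
        raise ValueError("scheme must be 'auto', 'exhaustive' or 'monte-carlo'")
    perm_cols = pooled[orders]  # (B, N)

    perm_f = _perm_moderated_f(X, perm_cols, sizes, s0_anova)
    q, c_star = permutation_fdr(f_mod, perm_f, q_star)
    return AnovaResult(
        protein_ids=quant.protein_ids,
        gene_symbols=quant.gene_symbols,
        groups=list(design.groups),
        f_stat=f_mod,
        p_parametric=p,
        q_value=q,
        significant=q <= q_star,
        s0_anova=s0_anova,
        n_permutations=perm_cols.shape[0],
        q_star=q_star,
        cutoff=c_star,
        seed=seed,
        permutation_scheme=scheme,
    )


def _perm_moderated_f(X: np.ndarray, perm_cols: np.ndarray, sizes: "list[int]", s0_anova: float) -> np.ndarray:
    """F' for every permutation: returns (B, m)."""
    k = len(sizes)
    N = sum(sizes)
    bounds = np.cumsum([0] + list(sizes))
    Y = X[:, perm_cols]  # (m, B, N)
    grand = Y.mean(axis=2)
    ss_between = np.zeros(grand.shape)
    ss_within = np.zeros(grand.shape)
    for g in range(k):
        block = Y[:, :, bounds[g]:bounds[g + 1]]
        mu = block.mean(axis=2)
        ss_between += sizes[g] * (mu - grand) ** 2
        ss_within += (sizes[g] - 1) * block.var(axis=2, ddof=1)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    denom = np.sqrt(ms_within) + s0_anova
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, ms_between / np.where(denom > 0, denom, 1.0) ** 2, np.inf)
    f = np.where((denom == 0) & (ms_between == 0), 0.0, f)
    return f.T


# ---------------------------------------------------------------------------
# multiple testing, volcano geometry, qPCR utility
# ---------------------------------------------------------------------------

def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni step-down (Holm) adjusted p-values, original order.

    With p-values sorted ascending, adjusted p_(i) is the running
    maximum of ``min(1, (m - j + 1) * p_(j))`` for ``j <= i``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def volcano_boundary(s0: float, cutoff: float, df: int, fc_grid) -> np.ndarray:
    """Significance boundary of the volcano plot in (fc, -log10 p) space.

    A protein sits exactly on the boundary when its moderated statistic
    equals the cutoff ``c*``; at fold change ``fc`` this corresponds to
    a classical t of ``t_b = fc*c*/(fc - c**s0)``, defined only for
    ``fc > c**s0`` (below that, |d| can never reach c*).  Returns an
    array of ``(fc, -log10 p)`` rows for the feasible grid points.
    """
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise ValueError("cutoff c* must be positive and finite")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    fc = np.asarray(fc_grid, dtype=float)
    feasible = fc > cutoff * s0
    fc = fc[feasible]
    t_b = fc * cutoff / (fc - cutoff * s0)
    p = 2.0 * sps.t.sf(t_b, df)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return np.column_stack([fc, neglog])


def ddct_fold_change(
    ct_target_treated: float,
    ct_housekeeping_treated: float,
    ct_target_control: float,
    ct_housekeeping_control: float,
) -> float:
    """Relative expression by the ddCt method: fold change = 2**(-ddCt)."""
    cts = [
        ct_target_treated,
        ct_housekeeping_treated,
        ct_target_control,
        ct_housekeeping_control,
    ]
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_housekeeping_treated) - (
        ct_target_control - ct_housekeeping_control
    )
    return float(2.0 ** (-ddct))
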