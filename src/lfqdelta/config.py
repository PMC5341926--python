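"""Pipeline configuration.

All tunable thresholds of the differential-analysis workflow live here,
with the defaults of the standard Perseus-style label-free workflow:
three valid values per group, downshifted-normal imputation at width
0.3·SD / downshift 1.8·SD, s0 = 0.5 with 250 permutations and a 5% FDR
for the pairwise tests, 5% FDR for the multi-group test, six clusters,
and gene-set term filters of ≥2 genes and ≥10% coverage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Parameters controlling every stage of the pipeline.

    Attributes
    ----------
    min_valid
        Minimum unmasked values required in at least one group.
    impute_width, impute_downshift
        Downshifted-normal imputation: draws come from
        ``Normal(m_c - downshift*s_c, (width*s_c)^2)`` per column ``c``.
    s0
        Fold-change damping constant of the moderated statistic
        ``d = delta / (se + s0)``.
    n_permutations
        Number of sample-label permutations (B) for FDR estimation.
    fdr_q, anova_fdr_q
        Significance thresholds (q*) for pairwise contrasts and for the
        multi-group test.
    s0_anova
        Moderation constant of the multi-group statistic (0 = classical F).
    n_clusters
        k for hierarchical clustering of multi-group-significant proteins.
    linkage_method
        Agglomeration linkage ('average', 'complete' or 'ward').
    enrichment_min_genes, enrichment_min_coverage
        Term filters: minimum overlap size and minimum fraction of a
        term's members present in the query.
    control_group
        Group used as the reference in contrasts; None = first group in
        the design.
    rng_seed
        Single integer fixing all imputation and permutation draws.
    """

    min_valid: int = 3
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    s0: float = 0.5
    n_permutations: int = 250
    fdr_q: float = 0.05
    anova_fdr_q: float = 0.05
    s0_anova: float = 0.0
    n_clusters: int = 6
    linkage_method: str = "average"
    enrichment_min_genes: int = 2
    enrichment_min_coverage: float = 0.10
    control_group: str | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_valid < 1:
            raise ValueError("min_valid must be >= 1")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be > 0")
        if self.impute_downshift < 0:
            raise ValueError("impute_downshift must be >= 0")
        if self.s0 < 0 or self.s0_anova < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for name in ("fdr_q", "anova_fdr_q"):
            q = getattr(self, name)
            if not (0 < q <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.linkage_method not in ("average", "complete", "ward"):
            raise ValueError("linkage_method must be average, complete or ward")
        if self.enrichment_min_genes < 0:
            raise ValueError("enrichment_min_genes must be >= 0")
        if not (0 <= self.enrichment_min_coverage <= 1):
            raise ValueError("enrichment_min_coverage must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
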