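"""Preprocessing: log transform, valid-value filtering, MNAR imputation,
row z-scoring.

Missing label-free intensities are overwhelmingly left-censored — the
protein was near or below the detection limit — so they are imputed from
a narrowed, down-shifted version of each sample column's observed
distribution (``Normal(m_c - d*s_c, (w*s_c)^2)``), which places the
imputed values where low-abundance measurements would plausibly fall.
Column statistics are computed from observed values only, before any
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import QuantMatrix, SampleDesign, Stage

__all__ = [
    "ImputationParams",
    "log2_transform",
    "filter_min_valid",
    "impute_downshifted_normal",
    "zscore_rows",
]


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-normal imputation parameters.

    ``width`` is the SD of the imputation distribution as a fraction of
    the column SD; ``downshift`` is the left shift of its mean in column
    SD units.  Defaults (0.3, 1.8) are the de-facto standard for this
    workflow style.
    """

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


def log2_transform(quant: QuantMatrix) -> QuantMatrix:
    """Replace each unmasked intensity by its base-2 logarithm.

    The matrix must be at stage ``raw`` with all unmasked values > 0
    (zeros should already be masked as missing by the reader).
    """
    quant.require_stage(Stage.RAW)
    observed = ~quant.missing_mask
    if np.any(quant.values[observed] <= 0):
        bad = np.argwhere(observed & (quant.values <= 0))[0]
        raise ValueError(
            f"non-positive unmasked intensity at protein "
            f"{quant.protein_ids[bad[0]]!r}, sample {quant.sample_ids[bad[1]]!r}"
        )
    values = np.full_like(quant.values, np.nan)
    values[observed] = np.log2(quant.values[observed])
    return quant.advance(Stage.LOG2, values)


def filter_min_valid(
    quant: QuantMatrix, design: SampleDesign, min_valid: int = 3
) -> QuantMatrix:
    """Keep proteins with >= ``min_valid`` valid values in at least one group.

    Row order is preserved.  ``min_valid`` larger than every group would
    make the filter vacuous and is rejected.
    """
    quant.require_stage(Stage.LOG2)
    if min_valid < 1:
        raise ValueError("min_valid must be >= 1")
    sizes = design.group_sizes()
    if min_valid > max(sizes.values()):
        raise ValueError(
            f"min_valid={min_valid} exceeds the largest group size "
            f"({max(sizes.values())}); no protein could ever pass"
        )
    design.validate_covers(quant)
    keep = np.zeros(quant.n_proteins, dtype=bool)
    valid = ~quant.missing_mask
    for g in design.groups:
        cols = design.column_indices(quant, g)
        if cols.size:
            keep |= valid[:, cols].sum(axis=1) >= min_valid
    return quant.subset_rows(np.flatnonzero(keep))


def impute_downshifted_normal(
    quant: QuantMatrix, params: ImputationParams | None = None, **kwargs
) -> QuantMatrix:
    """Impute masked cells from a per-column downshifted normal.

    For column ``c`` with observed mean ``m_c`` and SD ``s_c`` (ddof=1),
    each masked cell is replaced by an independent draw from
    ``Normal(m_c - downshift*s_c, (width*s_c)^2)``.  Unmasked values are
    untouched; the returned matrix records which cells were imputed in
    ``imputed_mask``.  Fully deterministic given ``params.seed``.
    """
    quant.require_stage(Stage.LOG2)
    if params is None:
        params = ImputationParams(**kwargs)
    rng = np.random.default_rng(params.seed)
    values = quant.values.copy()
    observed = ~quant.missing_mask
    n_obs = observed.sum(axis=0)
    for j in np.flatnonzero(n_obs < 2):
        raise ValueError(
            f"column {quant.sample_ids[j]!r} has {n_obs[j]} observed values; "
            "need >=2 to estimate its distribution"
        )
    for j in range(quant.n_samples):
        col = quant.values[:, j]
        obs = col[observed[:, j]]
        miss = np.flatnonzero(quant.missing_mask[:, j])
        if miss.size == 0:
            continue
        m_c = obs.mean()
        s_c = obs.std(ddof=1)
        values[miss, j] = rng.normal(
            m_c - params.downshift * s_c, params.width * s_c, size=miss.size
        )
    # after imputation every cell holds a value: the mask empties and the
    # formerly-missing cells are recorded in imputed_mask instead
    return quant.advance(
        Stage.IMPUTED,
        values,
        imputed_mask=quant.missing_mask.copy(),
        missing_mask=np.zeros_like(quant.missing_mask),
    )


def zscore_rows(quant: QuantMatrix) -> QuantMatrix:
    """Center and scale each protein row to mean 0, SD 1 (divisor n).

    Population SD is used deliberately: clustering distances depend on
    the divisor and this fixes the convention.  Constant rows cannot be
    scaled and raise, naming the protein.
    """
    quant.require_stage(Stage.IMPUTED)
    if np.any(quant.missing_mask):
        raise ValueError("z-scoring requires a fully imputed matrix")
    mean = quant.values.mean(axis=1, keepdims=True)
    sd = quant.values.std(axis=1, keepdims=True)  # ddof=0
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = [quant.protein_ids[i] for i in flat[:5]]
        raise ValueError(f"constant rows cannot be z-scored: {names}")
    return quant.advance(Stage.ZSCORED, (quant.values - mean) / sd)
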