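import numpy as np
import pytest

from lfqdelta import (
    ImputationParams,
    QuantMatrix,
    SampleDesign,
    SimulationParams,
    Stage,
    generate_lfq_dataset,
)
from lfqdelta.preprocess import (
    filter_min_valid,
    impute_downshifted_normal,
    log2_transform,
)


def make_quant(values, stage=Stage.LOG2, mask=None, sample_ids=None, genes=None):
    """Small QuantMatrix builder for tests."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    n, m = values.shape
    return QuantMatrix(
        protein_ids=[f"P{i}" for i in range(n)],
        gene_symbols=genes or [f"G{i}" for i in range(n)],
        values=values,
        missing_mask=np.asarray(mask, dtype=bool),
        stage=stage,
        sample_ids=sample_ids or [f"S{j}" for j in range(m)],
    )


def make_design(groups):
    """Design from {group: n_replicates}."""
    pairs = []
    for g, n in groups.items():
        for r in range(n):
            pairs.append((f"{g}_{r + 1}", g))
    return SampleDesign.from_groups(pairs)


@pytest.fixture
def two_group_design():
    return make_design({"CTR": 3, "T1": 3})


@pytest.fixture
def three_group_design():
    return make_design({"CTR": 3, "IFNG": 3, "IL27": 3})


def preprocessed_null(n_proteins=500, groups=None, seed=0, complete=True):
    """Generate a null dataset and run it through log2/filter/impute."""
    params = SimulationParams(
        n_proteins=n_proteins,
        groups=groups or {"CTR": 3, "T1": 3},
        affected_fraction=0.0,
        missing_midpoint=0.0 if complete else 21.0,
        seed=seed,
    )
    quant, design, truth = generate_lfq_dataset(params)
    quant = log2_transform(quant)
    quant = filter_min_valid(quant, design, 3)
    quant = impute_downshifted_normal(quant, ImputationParams(seed=seed))
    return quant, design, truth
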