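"""Synthetic label-free datasets with known ground truth.

The generator emulates the statistical structure of a three-condition
LFQ experiment (control plus two cytokine treatments, three biological
replicates each): log-normal protein intensities (normal on the log2
scale), per-group mean shifts for an "affected" subset of proteins whose
direction is shared between the two treatments with a configurable
concordance probability, replicate noise, and missingness whose
probability rises as intensity falls — a logistic
missing-not-at-random model mimicking values dropping below the
detection limit.  Every draw is fixed by a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSet, GeneSetCollection, QuantMatrix, SampleDesign, Stage

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "generate_lfq_dataset",
    "apply_mnar_missingness",
    "spike_enriched_geneset",
]


@dataclass
class SimulationParams:
    """Parameters of the synthetic LFQ generator.

    Attributes
    ----------
    n_proteins
        Number of protein groups (the study-scale proteome is several
        thousand; 2,000 keeps simulations fast while preserving the
        multiple-testing regime).
    groups
        Ordered mapping group label → replicate count.  The first group
        is the untreated control; the remaining groups are treatments.
    baseline_mean, baseline_sd
        Per-protein baseline log2 intensity ~ Normal(mu0, tau^2).
        Defaults (25, 2) match typical MaxQuant LFQ log2 scales.
    noise_sd
        Replicate noise SD on the log2 scale (0.3 ~ typical biological
        replicate scatter in LFQ).
    affected_fraction
        Fraction of proteins receiving a treatment effect.
    effect_low, effect_high
        Effect magnitudes (|log2 shift|) are Uniform(low, high); the
        sign is random per protein.
    concordance_fraction
        Probability that an affected protein moves in the same
        direction under the first two treatments.
    missing_midpoint, missing_slope
        Logistic MNAR model: a cell of log2 intensity x is masked with
        probability 1/(1 + exp(slope*(x - midpoint))).  The default
        midpoint sits in the low-abundance tail of the baseline
        distribution so that overall missingness is modest and
        concentrated at low intensities.
    seed
        Single integer fixing the whole dataset.
    """

    n_proteins: int = 2000
    groups: "dict[str, int]" = field(
        default_factory=lambda: {"CTR": 3, "IFNG": 3, "IL27": 3}
    )
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    affected_fraction: float = 0.10
    effect_low: float = 1.0
    effect_high: float = 3.0
    concordance_fraction: float = 0.8
    missing_midpoint: float = 21.0
    missing_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if len(self.groups) < 2:
            raise ValueError("need >=2 groups")
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("replicate counts must be >= 2")
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_sd and noise_sd must be > 0")
        for name in ("affected_fraction", "concordance_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.effect_low <= self.effect_high):
            raise ValueError("need 0 < effect_low <= effect_high")
        if self.missing_slope < 0:
            raise ValueError("missing_slope must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth aligned 1:1 with the generated proteins."""

    protein_ids: list[str]
    gene_symbols: list[str]
    baseline: np.ndarray
    effects: "dict[str, np.ndarray]"  # per treatment group, log2 shift
    affected: np.ndarray  # bool per protein
    concordance_class: list[str]  # concordant-up/-down, discordant, none
    missing_mask: np.ndarray | None = None

    @property
    def affected_genes(self) -> list[str]:
        return [g for g, a in zip(self.gene_symbols, self.affected) if a]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "protein_id": self.protein_ids,
            "gene": self.gene_symbols,
            "baseline_log2": self.baseline,
            "affected": self.affected,
            "concordance_class": self.concordance_class,
        }
        for g, eff in self.effects.items():
            cols[f"effect_{g}"] = eff
        return pd.DataFrame(cols)


def generate_lfq_dataset(
    params: SimulationParams | None = None, **kwargs
) -> "tuple[QuantMatrix, SampleDesign, SyntheticTruth]":
    """Generate a raw-scale LFQ dataset with known ground truth.

    The log2-scale cell value is ``baseline + effect(group) + noise``;
    values are exported on the linear scale (2**x) as a raw
    :class:`QuantMatrix`, after which logistic MNAR missingness is
    applied.  Identical parameters and seed give identical output.
    """
    if params is None:
        params = SimulationParams(**kwargs)
    rng = np.random.default_rng(params.seed)
    m = params.n_proteins
    group_names = list(params.groups)
    control = group_names[0]
    treatments = group_names[1:]

    protein_ids = [f"P{i:05d}" for i in range(m)]
    gene_symbols = [f"GENE{i:05d}" for i in range(m)]
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=m)

    affected = rng.random(m) < params.affected_fraction
    effects = {g: np.zeros(m) for g in treatments}
    classes = ["none"] * m
    idx = np.flatnonzero(affected)
    if idx.size and treatments:
        sign1 = rng.choice([-1.0, 1.0], size=idx.size)
        for t_i, t in enumerate(treatments):
            mag = rng.uniform(params.effect_low, params.effect_high, size=idx.size)
            if t_i == 0:
                sign = sign1
            elif t_i == 1:
                same = rng.random(idx.size) < params.concordance_fraction
                sign = np.where(same, sign1, -sign1)
            else:
                sign = rng.choice([-1.0, 1.0], size=idx.size)
            effects[t][idx] = sign * mag
        if len(treatments) >= 2:
            s1 = np.sign(effects[treatments[0]][idx])
            s2 = np.sign(effects[treatments[1]][idx])
            for j, p in enumerate(idx):
                if s1[j] == s2[j]:
                    classes[p] = "concordant-up" if s1[j] > 0 else "concordant-down"
                else:
                    classes[p] = "discordant"
        else:
            for j, p in enumerate(idx):
                classes[p] = (
                    "concordant-up" if effects[treatments[0]][p] > 0 else "concordant-down"
                )

    sample_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for g in group_names:
        shift = effects.get(g, np.zeros(m))
        for r in range(params.groups[g]):
            sid = f"{g}_{r + 1}"
            sample_ids.append(sid)
            pairs.append((sid, g))
            columns.append(baseline + shift + rng.normal(0, params.noise_sd, size=m))
    log2_values = np.column_stack(columns)

    quant = QuantMatrix(
        protein_ids=protein_ids,
        gene_symbols=gene_symbols,
        values=2.0 ** log2_values,
        missing_mask=np.zeros_like(log2_values, dtype=bool),
        stage=Stage.RAW,
        sample_ids=sample_ids,
    )
    mnar_seed = int(rng.integers(0, 2**31 - 1))
    quant = apply_mnar_missingness(
        quant, params.missing_midpoint, params.missing_slope, seed=mnar_seed
    )
    truth = SyntheticTruth(
        protein_ids=protein_ids,
        gene_symbols=gene_symbols,
        baseline=baseline,
        effects=effects,
        affected=affected,
        concordance_class=classes,
        missing_mask=quant.missing_mask.copy(),
    )
    return quant, SampleDesign.from_groups(pairs), truth


def apply_mnar_missingness(
    quant: QuantMatrix, m50: float, beta: float, seed: int = 0
) -> QuantMatrix:
    """Mask cells with probability decreasing in intensity.

    Each unmasked cell of log2 intensity x is masked independently with
    probability ``1/(1 + exp(beta*(x - m50)))``: 0.5 at the midpoint,
    approaching a hard detection threshold as beta grows, constant 0.5
    at beta = 0.  Works on raw- or log2-stage matrices; already-masked
    cells stay masked.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if quant.stage not in (Stage.RAW, Stage.LOG2):
        raise ValueError("MNAR missingness applies to raw or log2 matrices")
    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.log2(quant.values) if quant.stage is Stage.RAW else quant.values
    # numerically stable logistic
    p_missing = 1.0 / (1.0 + np.exp(np.clip(beta * (x - m50), -700, 700)))
    draws = rng.random(quant.values.shape)
    new_mask = quant.missing_mask | (~quant.missing_mask & (draws < p_missing))
    values = quant.values.copy()
    values[new_mask] = np.nan
    return dataclasses.replace(quant, values=values, missing_mask=new_mask)


def spike_enriched_geneset(
    truth: SyntheticTruth,
    universe,
    term_size: int,
    overlap_target: int,
    n_decoys: int = 20,
    seed: int = 0,
) -> GeneSetCollection:
    """Build a collection with one term enriched in affected genes.

    The spiked term contains ``overlap_target`` genes sampled from the
    truth's affected set and ``term_size - overlap_target`` unaffected
    genes; decoy terms of the same size are sampled uniformly from the
    universe, so their overlap with any affected-derived query is at
    chance level.
    """
    universe = sorted({g.strip().upper() for g in universe})
    if term_size > len(universe):
        raise ValueError("term_size exceeds universe size")
    if overlap_target > term_size:
        raise ValueError("overlap_target cannot exceed term_size")
    affected = [g.upper() for g in truth.affected_genes if g.upper() in set(universe)]
    unaffected = [g for g in universe if g not in set(affected)]
    if overlap_target > len(affected):
        raise ValueError(
            f"only {len(affected)} affected genes available for overlap "
            f"target {overlap_target}"
        )
    if term_size - overlap_target > len(unaffected):
        raise ValueError("not enough unaffected genes to pad the spiked term")
    rng = np.random.default_rng(seed)
    spike = list(rng.choice(affected, size=overlap_target, replace=False)) + list(
        rng.choice(unaffected, size=term_size - overlap_target, replace=False)
    )
    terms = [GeneSet("SPIKE", "spiked term enriched in affected genes", tuple(spike))]
    for i in range(n_decoys):
        members = rng.choice(universe, size=term_size, replace=False)
        terms.append(GeneSet(f"DECOY{i:03d}", "uniformly sampled decoy", tuple(members)))
    return GeneSetCollection(terms=terms, universe=list(universe))
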