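"""Core in-memory containers for label-free quantitation analysis.

The central object is :class:`QuantMatrix`, a protein-group × sample
intensity matrix with an explicit missingness mask and a processing-stage
flag.  The stage flag (``raw`` → ``log2`` → ``imputed`` → ``zscored``)
enforces the one-directional order of the preprocessing pipeline: raw
linear-scale intensities are log-transformed, missing cells are imputed,
and rows are z-scored only for clustering.  A "valid value" in the
filtering sense is an unmasked cell.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "QuantMatrix",
    "SampleDesign",
    "GeneSet",
    "GeneSetCollection",
    "StageError",
    "FormatError",
]


class StageError(ValueError):
    """An operation was applied to a QuantMatrix at the wrong stage."""


class FormatError(ValueError):
    """An input file violates its expected format."""


class Stage(str, enum.Enum):
    """Processing stage of a :class:`QuantMatrix`."""

    RAW = "raw"
    LOG2 = "log2"
    IMPUTED = "imputed"
    ZSCORED = "zscored"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]


_STAGE_ORDER = {Stage.RAW: 0, Stage.LOG2: 1, Stage.IMPUTED: 2, Stage.ZSCORED: 3}


@dataclass
class QuantMatrix:
    """Protein-group × sample intensity matrix with missingness mask.

    Parameters
    ----------
    protein_ids
        Unique accession strings, one per row.
    gene_symbols
        Gene symbol per row (may be empty strings).
    values
        Intensity matrix, shape ``(n_proteins, n_samples)``.  Linear scale
        at stage ``raw``, base-2 logarithms afterwards.  Masked cells hold
        NaN and are excluded from every statistic.
    missing_mask
        Boolean matrix, same shape; ``True`` marks a cell that was not
        quantified.
    stage
        Processing stage; transitions are one-directional.
    sample_ids
        Column labels.
    imputed_mask
        After imputation, which cells hold imputed draws (None before).
    """

    protein_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    stage: Stage
    sample_ids: list[str]
    imputed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.stage = Stage(self.stage)
        self.protein_ids = list(self.protein_ids)
        self.gene_symbols = list(self.gene_symbols)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape "
                f"{self.missing_mask.shape}"
            )
        if len(self.protein_ids) != self.values.shape[0]:
            raise ValueError("protein_ids length must match row count")
        if len(self.gene_symbols) != self.values.shape[0]:
            raise ValueError("gene_symbols length must match row count")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length must match column count")
        seen: set[str] = set()
        for pid in self.protein_ids:
            if pid in seen:
                raise FormatError(f"duplicate protein id: {pid!r}")
            seen.add(pid)
        # masked cells are NaN so they can never leak into statistics
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_stage(self, expected: Stage) -> None:
        if self.stage is not Stage(expected):
            raise StageError(
                f"expected stage {Stage(expected).value!r}, got {self.stage.value!r}"
            )

    def advance(self, new_stage: Stage, values: np.ndarray, **changes) -> "QuantMatrix":
        """Return a copy at ``new_stage`` with ``values`` replaced.

        Stage transitions must move forward (raw→log2→imputed→zscored).
        """
        new_stage = Stage(new_stage)
        if new_stage.order <= self.stage.order:
            raise StageError(
                f"cannot move from stage {self.stage.value!r} to {new_stage.value!r}"
            )
        changes.setdefault("missing_mask", self.missing_mask.copy())
        return replace(self, stage=new_stage, values=values, **changes)

    def subset_rows(self, row_index: np.ndarray) -> "QuantMatrix":
        """Row-subset preserving order; ``row_index`` is an integer index."""
        row_index = np.asarray(row_index)
        return replace(
            self,
            protein_ids=[self.protein_ids[i] for i in row_index],
            gene_symbols=[self.gene_symbols[i] for i in row_index],
            values=self.values[row_index],
            missing_mask=self.missing_mask[row_index],
            imputed_mask=None
            if self.imputed_mask is None
            else self.imputed_mask[row_index],
        )

    def to_frame(self) -> pd.DataFrame:
        """Intensities as a DataFrame (NaN = missing), proteins as index."""
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )


@dataclass
class SampleDesign:
    """Assignment of samples to experimental groups.

    ``groups`` preserves first-appearance order; the first group is the
    conventional control unless a config overrides it.
    """

    sample_ids: list[str]
    group_of: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = [s for s in self.sample_ids if self.sample_ids.count(s) > 1]
            raise FormatError(f"duplicate sample id: {dupes[0]!r}")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group: {missing}")
        if not self.groups:
            seen: list[str] = []
            for s in self.sample_ids:
                g = self.group_of[s]
                if g not in seen:
                    seen.append(g)
            self.groups = seen
        for g in self.groups:
            if not any(self.group_of[s] == g for s in self.sample_ids):
                raise ValueError(f"group {g!r} has no samples")

    @classmethod
    def from_groups(cls, assignments: "list[tuple[str, str]]") -> "SampleDesign":
        """Build from ``(sample_id, group)`` pairs in file order."""
        sample_ids = [s for s, _ in assignments]
        return cls(sample_ids=sample_ids, group_of=dict(assignments))

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"group {group!r} not in design")
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def column_indices(self, quant: QuantMatrix, group: str) -> np.ndarray:
        """Column indices of ``group``'s samples within ``quant``."""
        members = set(self.samples_in(group))
        idx = [j for j, s in enumerate(quant.sample_ids) if s in members]
        return np.asarray(idx, dtype=int)

    def validate_covers(self, quant: QuantMatrix) -> None:
        uncovered = [s for s in quant.sample_ids if s not in self.group_of]
        if uncovered:
            raise ValueError(f"design does not cover samples: {uncovered}")

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups}


@dataclass(frozen=True)
class GeneSet:
    """One flat gene set (term)."""

    term_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        # deduplicate, preserve order, uppercase symbols for exact matching
        seen: list[str] = []
        for g in self.genes:
            gu = g.strip().upper()
            if gu and gu not in seen:
                seen.append(gu)
        object.__setattr__(self, "genes", tuple(seen))


@dataclass
class GeneSetCollection:
    """A flat gene-set collection (GMT-style), optionally with a universe."""

    terms: list[GeneSet]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            dupes = [i for i in ids if ids.count(i) > 1]
            raise FormatError(f"duplicate term id: {dupes[0]!r}")
        if self.universe is not None:
            self.universe = sorted({g.strip().upper() for g in self.universe})

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)
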