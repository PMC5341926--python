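"""Readers and writers for the pipeline's tabular formats.

Input side: MaxQuant-style ``proteinGroups`` tables (tab-separated, one
intensity column per sample selected by a column-name prefix such as
``"LFQ intensity "``), two-column sample-design tables, and GMT gene-set
files.  Output side: the result tables of a pipeline run as TSV, with a
JSON sidecar recording the configuration and seed for audit.

Zero intensities are treated as missing, following the MaxQuant
convention for unquantified proteins (log2 of 0 is undefined and
Perseus-style workflows mask zeros the same way).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import (
    FormatError,
    GeneSet,
    GeneSetCollection,
    QuantMatrix,
    SampleDesign,
    Stage,
)

__all__ = [
    "read_protein_table",
    "read_design",
    "read_gmt",
    "write_gmt",
    "write_results",
    "write_protein_table",
    "write_design",
]

#: MaxQuant flag columns conventionally used to drop decoy/contaminant rows.
DEFAULT_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


def read_protein_table(
    path: str | Path,
    intensity_prefix: str = "LFQ intensity ",
    drop_flag_columns: "list[str] | tuple[str, ...] | None" = None,
    id_column: str = "Protein IDs",
    gene_column: str = "Gene names",
) -> QuantMatrix:
    """Read a MaxQuant-style protein-groups table into a raw QuantMatrix.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    intensity_prefix
        Columns whose names start with this prefix become sample columns;
        the sample id is the remainder of the column name.
    drop_flag_columns
        Rows carrying any non-empty marker in one of these columns (e.g.
        ``Reverse``, ``Potential contaminant``) are removed.  Columns not
        present in the file are ignored.  ``None`` disables row dropping.
    id_column, gene_column
        Protein accession and gene-symbol columns.  A missing gene column
        yields empty symbols.

    Cells that are empty, non-numeric, or exactly 0 are masked as missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    intensity_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not intensity_cols:
        raise FormatError(
            f"no columns start with intensity prefix {intensity_prefix!r}"
        )
    if id_column not in df.columns:
        raise FormatError(f"missing protein id column {id_column!r}")

    if drop_flag_columns:
        present = [c for c in drop_flag_columns if c in df.columns]
        if present:
            flagged = np.zeros(len(df), dtype=bool)
            for c in present:
                flagged |= df[c].str.strip().ne("").to_numpy()
            df = df.loc[~flagged].reset_index(drop=True)

    values = df[intensity_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    missing = ~np.isfinite(values) | (values == 0)

    protein_ids = df[id_column].tolist()
    seen: set[str] = set()
    for pid in protein_ids:
        if pid in seen:
            raise FormatError(f"duplicate protein id: {pid!r}")
        seen.add(pid)
    if gene_column in df.columns:
        genes = df[gene_column].str.strip().tolist()
    else:
        genes = [""] * len(df)

    sample_ids = [c[len(intensity_prefix):] for c in intensity_cols]
    return QuantMatrix(
        protein_ids=protein_ids,
        gene_symbols=genes,
        values=values,
        missing_mask=missing,
        stage=Stage.RAW,
        sample_ids=sample_ids,
    )


def write_protein_table(
    quant: QuantMatrix,
    path: str | Path,
    intensity_prefix: str = "LFQ intensity ",
) -> None:
    """Write a raw-stage QuantMatrix as a MaxQuant-style TSV.

    Masked cells are written as 0 (the MaxQuant unquantified
    convention), so ``read_protein_table`` re-masks them on the way in.
    """
    quant.require_stage(Stage.RAW)
    df = pd.DataFrame({"Protein IDs": quant.protein_ids, "Gene names": quant.gene_symbols})
    values = np.where(quant.missing_mask, 0.0, quant.values)
    for j, sid in enumerate(quant.sample_ids):
        df[intensity_prefix + sid] = values[:, j]
    _write_tsv(df, Path(path))


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in design.sample_ids:
            fh.write(f"{s}\t{design.group_of[s]}\n")


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column (sample_id, group) tab-separated design table.

    A header line is optional: a first line reading ``sample<TAB>group``
    (case-insensitive) is skipped.  Groups keep first-appearance order.
    """
    lines = Path(path).read_text().splitlines()
    pairs: list[tuple[str, str]] = []
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {i + 1}: expected 2 tab-separated fields")
        sid, grp = fields[0].strip(), fields[1].strip()
        if i == 0 and sid.lower() in ("sample", "sample_id") and grp.lower() == "group":
            continue
        pairs.append((sid, grp))
    if not pairs:
        raise FormatError("empty design file")
    sids = [s for s, _ in pairs]
    for s in sids:
        if sids.count(s) > 1:
            raise FormatError(f"duplicate sample id: {s!r}")
    return SampleDesign.from_groups(pairs)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term_id TAB description TAB gene1 TAB gene2 ...``.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields is a format error.
    """
    terms: list[GeneSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"line {i + 1}: GMT line needs >=3 tab-separated fields"
            )
        terms.append(GeneSet(term_id=fields[0], name=fields[1], genes=tuple(fields[2:])))
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in collection:
            fh.write("\t".join([t.term_id, t.name, *t.genes]) + "\n")


# float format used by every result table: full round-trip precision
_FLOAT_FMT = "%.17g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_results(results, outdir: str | Path, config: PipelineConfig | None = None) -> "list[Path]":
    """Write a pipeline result bundle as TSV tables plus a JSON sidecar.

    ``results`` is a :class:`~lfqdelta.model.DifferentialProteomeResults`
    (duck-typed: any object exposing the same ``*_frame`` accessors).
    Returns the written paths.  Numbers are written with 17 significant
    digits so that re-reading reproduces every value exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame | None) -> None:
        if df is None:
            return
        p = outdir / name
        _write_tsv(df, p)
        written.append(p)

    emit("anova.tsv", results.anova_frame())
    for label, frame in results.contrast_frames().items():
        emit(f"contrast_{label}.tsv", frame)
    emit("clusters.tsv", results.cluster_frame())
    emit("concordance.tsv", results.concordance_frame())
    emit("concordance_counts.tsv", results.concordance_counts_frame())
    emit("pca.tsv", results.pca_frame())
    emit("correlogram.tsv", results.correlogram_frame())
    emit("correlogram_group_means.tsv", results.correlogram_group_means_frame())
    emit("enrichment.tsv", results.enrichment_frame())

    sidecar = {
        "config": (config or results.config).to_dict(),
        "tables": [p.name for p in written],
    }
    sidecar_path = outdir / "run.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    written.append(sidecar_path)
    return written
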