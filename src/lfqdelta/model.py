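"""Model/results interface to the full differential-analysis pipeline.

:class:`DifferentialProteomeModel` bundles a quantitation matrix, a
sample design, an optional gene-set collection and a
:class:`~lfqdelta.config.PipelineConfig`; :meth:`fit` executes the
stages in order

    log2 → min-valid filter → MNAR imputation
         → multi-group permutation test (q <= anova_fdr_q)
         → z-score + hierarchical clustering of the significant set
         → pairwise moderated-t contrasts (control vs each treatment,
           and between treatments) with s0 / B / fdr_q
         → concordance classification of the two treatments
         → PCA and Pearson correlogram of the samples
         → gene-set enrichment of each significant set

and returns a :class:`DifferentialProteomeResults` carrying every
stage's result object, a text ``summary()``, and ``save()`` for the
TSV + JSON-sidecar output bundle.  A single integer seed fixes all
imputation and permutation draws, so identical inputs and config give
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .config import PipelineConfig
from .containers import GeneSetCollection, QuantMatrix, SampleDesign, Stage
from .diffstats import (
    AnovaResult,
    ContrastResult,
    multi_group_anova,
    two_sample_contrast,
    volcano_boundary,
)
from .enrichment import EnrichmentResult, enrich_query, results_frame
from .preprocess import (
    ImputationParams,
    filter_min_valid,
    impute_downshifted_normal,
    log2_transform,
    zscore_rows,
)
from .structure import (
    ClusterResult,
    ConcordanceSummary,
    CorrelogramResult,
    PCAResult,
    classify_concordance,
    hierarchical_cluster,
    pca_scores,
    pearson_correlogram,
)

__all__ = ["DifferentialProteomeModel", "DifferentialProteomeResults", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """An error raised by a pipeline stage, annotated with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r}: {original}")
        self.stage = stage
        self.original = original


def _derive_seeds(rng_seed: int, labels: "list[str]") -> "dict[str, int]":
    """Independent per-stage integer seeds from the single run seed."""
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(labels))
    return {
        lab: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        for lab, c in zip(labels, children)
    }


class DifferentialProteomeModel:
    """Differential analysis of a label-free proteome across treatments.

    Parameters
    ----------
    quant
        Raw- or log2-stage quantitation matrix.
    design
        Sample-to-group assignment covering all of ``quant``'s samples;
        >=2 groups are required, each with >=2 samples for the
        permutation tests.
    genesets
        Optional flat gene-set collection; enables the enrichment stage.
    config
        Pipeline thresholds and the run seed (defaults mirror the
        standard workflow).
    """

    def __init__(
        self,
        quant: QuantMatrix,
        design: SampleDesign,
        genesets: GeneSetCollection | None = None,
        config: PipelineConfig | None = None,
    ):
        self.quant = quant
        self.design = design
        self.genesets = genesets
        self.config = config or PipelineConfig()
        design.validate_covers(quant)
        if len(design.groups) < 2:
            raise ValueError("need >=2 groups in the design")
        self.control = self.config.control_group or design.groups[0]
        if self.control not in design.groups:
            raise ValueError(f"control group {self.control!r} not in design")
        self.treatments = [g for g in design.groups if g != self.control]

    @classmethod
    def from_files(
        cls,
        table_path,
        design_path,
        gmt_path=None,
        config: PipelineConfig | None = None,
        intensity_prefix: str = "LFQ intensity ",
        drop_flag_columns=_io.DEFAULT_FLAG_COLUMNS,
    ) -> "DifferentialProteomeModel":
        """Build the model straight from the on-disk input files."""
        quant = _io.read_protein_table(
            table_path, intensity_prefix=intensity_prefix, drop_flag_columns=drop_flag_columns
        )
        design = _io.read_design(design_path)
        genesets = _io.read_gmt(gmt_path) if gmt_path else None
        return cls(quant, design, genesets, config)

    def fit(self) -> "DifferentialProteomeResults":
        cfg = self.config
        seeds = _derive_seeds(
            cfg.rng_seed,
            ["impute", "anova"]
            + [f"contrast_{i}" for i in range(len(self.design.groups) ** 2)],
        )

        def stage(name, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, exc) from exc

        q = self.quant
        if q.stage is Stage.RAW:
            q = stage("log2_transform", log2_transform, q)
        else:
            q.require_stage(Stage.LOG2)
        q = stage("filter_min_valid", filter_min_valid, q, self.design, cfg.min_valid)
        q = stage(
            "impute",
            impute_downshifted_normal,
            q,
            ImputationParams(cfg.impute_width, cfg.impute_downshift, seeds["impute"]),
        )

        anova = stage(
            "multi_group_anova",
            multi_group_anova,
            q,
            self.design,
            n_permutations=cfg.n_permutations,
            q_star=cfg.anova_fdr_q,
            seed=seeds["anova"],
            s0_anova=cfg.s0_anova,
        )

        clusters = None
        sig_ids = anova.significant_ids
        if sig_ids:
            sig_idx = [i for i, p in enumerate(q.protein_ids) if p in set(sig_ids)]
            sub = q.subset_rows(np.asarray(sig_idx, dtype=int))
            zs = stage("zscore_rows", zscore_rows, sub)
            k = min(cfg.n_clusters, zs.n_proteins)
            clusters = stage(
                "hierarchical_cluster", hierarchical_cluster, zs, k, cfg.linkage_method
            )

        contrasts: dict[str, ContrastResult] = {}
        pairs = [(self.control, t) for t in self.treatments]
        for i, t1 in enumerate(self.treatments):
            for t2 in self.treatments[i + 1:]:
                pairs.append((t1, t2))
        for i, (a, b) in enumerate(pairs):
            res = stage(
                "two_sample_contrast",
                two_sample_contrast,
                q,
                self.design,
                a,
                b,
                s0=cfg.s0,
                n_permutations=cfg.n_permutations,
                q_star=cfg.fdr_q,
                seed=seeds[f"contrast_{i}"],
            )
            contrasts[res.label] = res

        concordance = None
        if len(self.treatments) >= 2 and sig_ids:
            t1, t2 = self.treatments[0], self.treatments[1]
            concordance = stage(
                "classify_concordance",
                classify_concordance,
                contrasts[f"{t1}_vs_{self.control}"],
                contrasts[f"{t2}_vs_{self.control}"],
                sig_ids,
            )

        pca = stage("pca_scores", pca_scores, q, min(2, q.n_samples))
        correlogram = stage("pearson_correlogram", pearson_correlogram, q, self.design)

        enrichments: dict[str, list[EnrichmentResult]] = {}
        if self.genesets is not None:
            universe = sorted(
                {g.strip().upper() for g in q.gene_symbols if g.strip()}
            )
            gene_of = dict(zip(q.protein_ids, q.gene_symbols))

            def gene_query(ids):
                return sorted(
                    {gene_of[p].strip().upper() for p in ids if gene_of[p].strip()}
                )

            queries = {"anova_significant": gene_query(sig_ids)}
            for label, res in contrasts.items():
                ids = [p for p, s in zip(res.protein_ids, res.significant) if s]
                queries[label] = gene_query(ids)
            for label, genes in queries.items():
                if genes:
                    enrichments[label] = stage(
                        "enrich_query",
                        enrich_query,
                        genes,
                        self.genesets,
                        universe,
                        cfg.enrichment_min_genes,
                        cfg.enrichment_min_coverage,
                    )

        return DifferentialProteomeResults(
            config=cfg,
            design=self.design,
            control=self.control,
            treatments=list(self.treatments),
            quant=q,
            anova=anova,
            contrasts=contrasts,
            clusters=clusters,
            concordance=concordance,
            pca=pca,
            correlogram=correlogram,
            enrichments=enrichments,
        )


@dataclass
class DifferentialProteomeResults:
    """Everything a fitted pipeline produced, with table/plot accessors."""

    config: PipelineConfig
    design: SampleDesign
    control: str
    treatments: list[str]
    quant: QuantMatrix  # filtered + imputed matrix the tests ran on
    anova: AnovaResult
    contrasts: "dict[str, ContrastResult]"
    clusters: ClusterResult | None
    concordance: ConcordanceSummary | None
    pca: PCAResult
    correlogram: CorrelogramResult
    enrichments: "dict[str, list[EnrichmentResult]]" = field(default_factory=dict)

    # ---- table accessors -------------------------------------------------
    def anova_frame(self) -> pd.DataFrame:
        return self.anova.to_frame()

    def contrast_frames(self) -> "dict[str, pd.DataFrame]":
        return {label: res.to_frame() for label, res in self.contrasts.items()}

    def cluster_frame(self) -> pd.DataFrame | None:
        return None if self.clusters is None else self.clusters.to_frame()

    def concordance_frame(self) -> pd.DataFrame | None:
        return None if self.concordance is None else self.concordance.to_frame()

    def concordance_counts_frame(self) -> pd.DataFrame | None:
        return None if self.concordance is None else self.concordance.counts_frame()

    def pca_frame(self) -> pd.DataFrame:
        return self.pca.to_frame()

    def correlogram_frame(self) -> pd.DataFrame:
        return self.correlogram.to_frame()

    def correlogram_group_means_frame(self) -> pd.DataFrame:
        return self.correlogram.group_means_frame()

    def enrichment_frame(self) -> pd.DataFrame | None:
        if not self.enrichments:
            return None
        frames = []
        for label, results in self.enrichments.items():
            df = results_frame(results)
            df.insert(0, "query", label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    # ---- reporting -------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Differential proteome analysis",
            "==============================",
            f"proteins tested (after min-valid filter): {self.quant.n_proteins}",
            f"samples: {self.quant.n_samples}  groups: {', '.join(self.design.groups)}"
            f"  (control: {self.control})",
            f"config: s0={cfg.s0}  B={cfg.n_permutations}  q*={cfg.fdr_q}"
            f"  anova q*={cfg.anova_fdr_q}  min_valid={cfg.min_valid}"
            f"  seed={cfg.rng_seed}",
            "",
            f"multi-group test: {self.anova.n_significant} significant"
            f" (scheme: {self.anova.permutation_scheme})",
        ]
        for label, res in self.contrasts.items():
            lines.append(
                f"contrast {label}: {res.n_significant} significant"
                f" (c* = {res.cutoff:.4g}, scheme: {res.permutation_scheme})"
            )
        if self.concordance is not None:
            c = self.concordance.counts
            lines += [
                "",
                f"concordance ({self.treatments[0]} & {self.treatments[1]} vs"
                f" {self.control}) over {len(self.concordance.protein_ids)}"
                " multi-group-significant proteins:",
                f"  concordant: {self.concordance.n_concordant}"
                f" (up: {c['concordant-up']}, down: {c['concordant-down']})",
                f"  discordant: {c['discordant']}"
                + (f"  undirected: {c['undirected']}" if c["undirected"] else ""),
            ]
        evr = self.pca.explained_variance_ratio
        lines.append("")
        lines.append(
            "PCA explained variance: "
            + ", ".join(f"PC{i + 1} {v:.1%}" for i, v in enumerate(evr))
        )
        gm = self.correlogram.group_means
        pretty = ", ".join(f"{g}~{h}: {r:.3f}" for (g, h), r in gm.items())
        lines.append(f"mean Pearson r: {pretty}")
        if self.enrichments:
            lines.append("")
            for label, results in self.enrichments.items():
                top = [r for r in results if r.passed_filters][:3]
                desc = "; ".join(
                    f"{r.term_id} (p_adj={r.p_adjusted:.3g})" for r in top
                ) or "no term passed the filters"
                lines.append(f"enrichment [{label}]: {desc}")
        return "\n".join(lines)

    def save(self, outdir) -> "list":
        """Write all result tables and the config/seed sidecar to ``outdir``."""
        return _io.write_results(self, outdir, config=self.config)

    # ---- plots (best-effort conveniences) --------------------------------
    def plot_volcano(self, label: str, ax=None):
        """Volcano plot of one contrast with the s0/FDR significance curve."""
        import matplotlib.pyplot as plt

        res = self.contrasts[label]
        if ax is None:
            _, ax = plt.subplots()
        neglog = -np.log10(np.clip(res.p_parametric, 1e-300, None))
        ax.scatter(
            res.log2_fc, neglog,
            c=np.where(res.significant, "crimson", "0.6"), s=8, lw=0,
        )
        if np.isfinite(res.cutoff) and res.cutoff > 0:
            grid = np.linspace(res.cutoff * res.s0 + 1e-6, max(1.0, np.nanmax(np.abs(res.log2_fc))), 200)
            pts = volcano_boundary(res.s0, res.cutoff, res.df, grid)
            ax.plot(pts[:, 0], pts[:, 1], "k-", lw=1)
            ax.plot(-pts[:, 0], pts[:, 1], "k-", lw=1)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        ax.set_title(label)
        return ax

    def plot_pca(self, ax=None):
        """Sample scatter on the first two principal components."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        groups = [self.design.group_of[s] for s in self.pca.sample_ids]
        for g in self.design.groups:
            idx = [i for i, gg in enumerate(groups) if gg == g]
            ax.scatter(self.pca.scores[idx, 0], self.pca.scores[idx, 1], label=g)
        evr = self.pca.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
        if len(evr) > 1:
            ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
        ax.legend()
        return ax


def run_pipeline(
    config: PipelineConfig,
    quant: QuantMatrix,
    design: SampleDesign,
    genesets: GeneSetCollection | None = None,
) -> DifferentialProteomeResults:
    """Functional entry point: build the model and fit it in one call."""
    return DifferentialProteomeModel(quant, design, genesets, config).fit()
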