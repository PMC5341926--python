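"""Sample-level structure and expression-pattern analysis.

PCA and the Pearson correlogram describe how samples relate to each
other (replicates should cluster by treatment); hierarchical clustering
of z-scored protein profiles groups the significantly modulated
proteins by expression pattern; concordance classification splits the
modulated proteins of two treatments into concordant-up,
concordant-down and discordant sets relative to the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .containers import QuantMatrix, SampleDesign, Stage
from .diffstats import ContrastResult

__all__ = [
    "PCAResult",
    "CorrelogramResult",
    "ClusterResult",
    "ConcordanceSummary",
    "pca_scores",
    "pearson_correlogram",
    "hierarchical_cluster",
    "classify_concordance",
]


@dataclass
class PCAResult:
    """Per-sample principal-component scores and explained variance."""

    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def pca_scores(quant: QuantMatrix, n_components: int = 2) -> PCAResult:
    """Principal-component scores of the samples.

    Samples are the observations, proteins the variables; variables are
    mean-centered (no scaling), so adding a constant to one protein's
    row leaves the scores unchanged.
    """
    quant.require_stage(Stage.IMPUTED)
    n_samples, n_proteins = quant.n_samples, quant.n_proteins
    if n_samples < 2:
        raise ValueError("PCA needs >=2 samples")
    if not (1 <= n_components <= min(n_samples, n_proteins)):
        raise ValueError(
            f"n_components must be in [1, {min(n_samples, n_proteins)}]"
        )
    X = quant.values.T  # samples × proteins
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        sample_ids=list(quant.sample_ids),
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


@dataclass
class CorrelogramResult:
    """Sample × sample Pearson correlation matrix with group averages.

    ``group_means[(G, H)]`` is the mean coefficient over sample pairs
    with one sample in G and one in H; for G = H the diagonal is
    excluded (a sample's self-correlation is uninformative).
    """

    sample_ids: list[str]
    matrix: np.ndarray
    group_means: "dict[tuple[str, str], float]"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.sample_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def group_means_frame(self) -> pd.DataFrame:
        rows = [
            {"group_1": g, "group_2": h, "mean_pearson_r": r}
            for (g, h), r in self.group_means.items()
        ]
        return pd.DataFrame(rows)


def pearson_correlogram(quant: QuantMatrix, design: SampleDesign) -> CorrelogramResult:
    """Pearson correlations between all sample pairs, plus group averages."""
    quant.require_stage(Stage.IMPUTED)
    if quant.n_proteins < 2:
        raise ValueError("need >=2 proteins")
    sds = quant.values.std(axis=0)
    for j in np.flatnonzero(sds == 0):
        raise ValueError(f"sample {quant.sample_ids[j]!r} has zero variance")
    design.validate_covers(quant)
    corr = np.corrcoef(quant.values.T)
    np.fill_diagonal(corr, 1.0)

    group_means: dict[tuple[str, str], float] = {}
    for gi, g in enumerate(design.groups):
        cols_g = design.column_indices(quant, g)
        for h in design.groups[gi:]:
            cols_h = design.column_indices(quant, h)
            if g == h:
                vals = [
                    corr[i, j] for i in cols_g for j in cols_h if i < j
                ]
            else:
                vals = [corr[i, j] for i in cols_g for j in cols_h]
            if vals:
                group_means[(g, h)] = float(np.mean(vals))
    return CorrelogramResult(
        sample_ids=list(quant.sample_ids), matrix=corr, group_means=group_means
    )


@dataclass
class ClusterResult:
    """Hierarchical clustering of protein profiles cut into k clusters."""

    protein_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    assignment: np.ndarray  # cluster id in 1..k per protein
    k: int
    sample_ids: list[str]
    cluster_profiles: pd.DataFrame  # mean z-score per cluster × sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": self.protein_ids, "cluster": self.assignment}
        )

    def dendrogram_json(self) -> list:
        """Merge tree as nested lists: [left, right, height]; leaves are ids."""

        def build(node):
            if node.is_leaf():
                return self.protein_ids[node.id]
            return [build(node.left), build(node.right), node.dist]

        tree = hierarchy.to_tree(self.linkage)
        return build(tree)


def hierarchical_cluster(
    quant: QuantMatrix, k: int = 6, method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of z-scored protein rows, cut at k.

    Euclidean distances with average linkage by default ('complete' and
    'ward' available).  Deterministic for a given input order.
    """
    quant.require_stage(Stage.ZSCORED)
    if not (1 <= k <= quant.n_proteins):
        raise ValueError(f"k must be in [1, {quant.n_proteins}]")
    if method not in ("average", "complete", "ward"):
        raise ValueError("method must be average, complete or ward")
    Z = hierarchy.linkage(pdist(quant.values, metric="euclidean"), method=method)
    assignment = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    profiles = (
        pd.DataFrame(quant.values, columns=quant.sample_ids)
        .groupby(assignment)
        .mean()
        .rename_axis("cluster")
        .reset_index()
    )
    return ClusterResult(
        protein_ids=list(quant.protein_ids),
        linkage=Z,
        assignment=assignment,
        k=k,
        sample_ids=list(quant.sample_ids),
        cluster_profiles=profiles,
    )


@dataclass
class ConcordanceSummary:
    """Direction-of-change agreement between two treatments vs control.

    A protein is concordant-up when both treatments raise it relative
    to control, concordant-down when both lower it, discordant when the
    two treatments move it in opposite directions.  Proteins with an
    exactly zero fold change under either treatment land in a separate
    'undirected' bucket outside the three classes.
    """

    protein_ids: list[str]
    direction_1: np.ndarray  # +1 / -1 / 0 per protein
    direction_2: np.ndarray
    classes: list[str]
    treatment_1: str
    treatment_2: str

    @property
    def counts(self) -> "dict[str, int]":
        out = {"concordant-up": 0, "concordant-down": 0, "discordant": 0, "undirected": 0}
        for c in self.classes:
            out[c] += 1
        return out

    @property
    def n_concordant(self) -> int:
        c = self.counts
        return c["concordant-up"] + c["concordant-down"]

    @property
    def n_discordant(self) -> int:
        return self.counts["discordant"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                f"direction_{self.treatment_1}": self.direction_1,
                f"direction_{self.treatment_2}": self.direction_2,
                "class": self.classes,
            }
        )

    def counts_frame(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame(
            {"class": list(c.keys()), "count": list(c.values())}
        )


def classify_concordance(
    res1: ContrastResult,
    res2: ContrastResult,
    eligible: "list[str] | set[str]",
    require_significant: bool = False,
) -> ConcordanceSummary:
    """Classify each eligible protein by its direction under two treatments.

    ``res1``/``res2`` are treatment-vs-control contrasts; ``eligible``
    is the caller's set of modulated proteins (typically the
    multi-group-significant set).  Direction is the sign of the log2
    fold change; with ``require_significant`` a protein additionally
    needs a significant call in a contrast for that direction to count
    (otherwise its direction is 0 → 'undirected').
    """
    eligible_list = [p for p in res1.protein_ids if p in set(eligible)]
    missing = set(eligible) - set(res1.protein_ids)
    missing |= set(eligible) - set(res2.protein_ids)
    if missing:
        raise ValueError(f"eligible proteins absent from a contrast: {sorted(missing)[:5]}")

    idx1 = {p: i for i, p in enumerate(res1.protein_ids)}
    idx2 = {p: i for i, p in enumerate(res2.protein_ids)}

    def direction(res: ContrastResult, idx: dict, pid: str) -> int:
        i = idx[pid]
        if require_significant and not res.significant[i]:
            return 0
        return int(np.sign(res.log2_fc[i]))

    d1 = np.array([direction(res1, idx1, p) for p in eligible_list])
    d2 = np.array([direction(res2, idx2, p) for p in eligible_list])
    classes = []
    for a, b in zip(d1, d2):
        if a == 0 or b == 0:
            classes.append("undirected")
        elif a == b == 1:
            classes.append("concordant-up")
        elif a == b == -1:
            classes.append("concordant-down")
        else:
            classes.append("discordant")
    return ConcordanceSummary(
        protein_ids=eligible_list,
        direction_1=d1,
        direction_2=d2,
        classes=classes,
        treatment_1=res1.group_b,
        treatment_2=res2.group_b,
    )
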