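import numpy as np
import pytest

from lfqdelta import (
    classify_concordance,
    hierarchical_cluster,
    pca_scores,
    pearson_correlogram,
    two_sample_contrast,
)
from lfqdelta.diffstats import ContrastResult
from lfqdelta.preprocess import zscore_rows
from lfqdelta.simulate import SimulationParams, generate_lfq_dataset

from conftest import make_design, make_quant, preprocessed_null


def imputed(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    return make_quant(values, sample_ids=sample_ids).advance("imputed", values)


class TestPcaScores:
    def test_rank_one_data_explained_by_first_component(self):
        pattern = np.array([1.0, 2.0, 3.0, 4.0])
        weights = np.array([1.0, 0.5, 2.0, -1.0, 3.0])
        q = imputed(np.outer(weights, pattern))
        res = pca_scores(q, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_invariant_to_per_protein_constant_shift(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 5))
        shifted = values + rng.normal(size=(20, 1))  # constant per protein
        s1 = pca_scores(imputed(values), 2).scores
        s2 = pca_scores(imputed(shifted), 2).scores
        np.testing.assert_allclose(np.abs(s1), np.abs(s2), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        # brute-force oracle: eigenvectors of the sample covariance of the
        # centered samples-by-proteins matrix
        rng = np.random.default_rng(1)
        values = rng.normal(25, 2, size=(40, 6))
        res = pca_scores(imputed(values), n_components=3)
        X = values.T - values.T.mean(axis=0)
        cov = X @ X.T  # sample Gram matrix, same nonzero eigenvalues
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        oracle = v[:, order[:3]] * np.sqrt(w[order[:3]])
        for j in range(3):
            assert (
                np.allclose(res.scores[:, j], oracle[:, j], atol=1e-8)
                or np.allclose(res.scores[:, j], -oracle[:, j], atol=1e-8)
            )

    def test_out_of_range_components_rejected(self):
        q = imputed(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            pca_scores(q, n_components=4)


class TestPearsonCorrelogram:
    def test_duplicated_and_negated_samples(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        q = imputed(
            np.column_stack([base, base, -base]),
            sample_ids=["A_1", "A_2", "B_1"],
        )
        design = make_design({"A": 2, "B": 1})
        res = pearson_correlogram(q, design)
        assert res.matrix[0, 1] == pytest.approx(1.0)
        assert res.matrix[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(res.matrix), 1.0)

    def test_matrix_symmetric_bounded(self):
        quant, design, _ = preprocessed_null(n_proteins=100, seed=3)
        res = pearson_correlogram(quant, design)
        np.testing.assert_allclose(res.matrix, res.matrix.T, atol=1e-12)
        assert np.all(res.matrix <= 1 + 1e-12) and np.all(res.matrix >= -1 - 1e-12)

    def test_shared_effects_raise_between_treatment_correlation(self):
        # two treatments sharing most effects correlate better with each
        # other than either does with the control
        params = SimulationParams(
            n_proteins=800,
            affected_fraction=0.4,
            concordance_fraction=0.9,
            effect_low=2.0,
            effect_high=4.0,
            missing_midpoint=0.0,
            seed=5,
        )
        quant, design, _ = generate_lfq_dataset(params)
        from lfqdelta.preprocess import ImputationParams, impute_downshifted_normal, log2_transform

        quant = impute_downshifted_normal(log2_transform(quant), ImputationParams(seed=1))
        res = pearson_correlogram(quant, design)
        between_treat = res.group_means[("IFNG", "IL27")]
        assert between_treat > res.group_means[("CTR", "IFNG")]
        assert between_treat > res.group_means[("CTR", "IL27")]

    def test_zero_variance_sample_names_offender(self):
        q = imputed([[1.0, 2.0], [1.0, 3.0]], sample_ids=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_correlogram(q, make_design({"flat": 1, "ok": 1}))


class TestHierarchicalCluster:
    def zscored(self, values):
        return zscore_rows(imputed(values))

    def test_recovers_two_separated_profile_groups(self):
        rng = np.random.default_rng(7)
        up = np.array([-1, -1, 1, 1, 1, -1.0]) * 5
        down = -up
        values = np.vstack(
            [up + rng.normal(0, 0.1, 6) + 20 for _ in range(15)]
            + [down + rng.normal(0, 0.1, 6) + 20 for _ in range(10)]
        )
        res = hierarchical_cluster(self.zscored(values), k=2)
        first = set(res.assignment[:15])
        second = set(res.assignment[15:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_duplicate_rows_merge_at_height_zero(self):
        values = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 2.0]])
        res = hierarchical_cluster(self.zscored(values), k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert res.assignment[0] == res.assignment[1]

    def test_k_equal_n_gives_singletons(self):
        rng = np.random.default_rng(8)
        res = hierarchical_cluster(self.zscored(rng.normal(size=(6, 4))), k=6)
        assert sorted(res.assignment) == [1, 2, 3, 4, 5, 6]

    def test_assignment_invariant_to_row_shuffle(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(30, 5))
        res = hierarchical_cluster(self.zscored(values), k=4)
        perm = rng.permutation(30)
        res2 = hierarchical_cluster(self.zscored(values[perm]), k=4)
        # same partition up to relabeling
        pairs = {}
        for orig, new in zip(res.assignment[perm], res2.assignment):
            pairs.setdefault(orig, set()).add(new)
        assert all(len(v) == 1 for v in pairs.values())

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            hierarchical_cluster(self.zscored(rng.normal(size=(5, 4))), k=6)

    def test_cluster_profiles_cover_all_clusters(self):
        rng = np.random.default_rng(2)
        res = hierarchical_cluster(self.zscored(rng.normal(size=(40, 6))), k=6)
        assert set(res.cluster_profiles["cluster"]) == set(res.assignment)


def fake_contrast(protein_ids, fcs, treatment, control="CTR"):
    n = len(protein_ids)
    fcs = np.asarray(fcs, dtype=float)
    return ContrastResult(
        protein_ids=list(protein_ids),
        gene_symbols=[f"G{i}" for i in range(n)],
        group_a=control,
        group_b=treatment,
        log2_fc=fcs,
        se=np.ones(n),
        d_stat=fcs,
        p_parametric=np.full(n, 0.5),
        q_value=np.full(n, 0.5),
        significant=np.ones(n, dtype=bool),
        s0=0.5,
        n_permutations=18,
        q_star=0.05,
        cutoff=np.inf,
        seed=0,
    )


class TestClassifyConcordance:
    def test_direction_rules(self):
        ids = ["P0", "P1", "P2"]
        res1 = fake_contrast(ids, [2.0, 2.0, 0.0], "T1")
        res2 = fake_contrast(ids, [1.0, -1.0, 1.0], "T2")
        summary = classify_concordance(res1, res2, ids)
        assert summary.classes == ["concordant-up", "discordant", "undirected"]

    def test_counts_partition_eligible_set(self):
        ids = [f"P{i}" for i in range(10)]
        fc1 = [1, 1, 1, 1, -1, -1, -1, 1, -1, 1]
        fc2 = [2, 2, 2, 2, -2, -2, -2, -2, 2, -2]
        summary = classify_concordance(
            fake_contrast(ids, fc1, "T1"), fake_contrast(ids, fc2, "T2"), ids
        )
        c = summary.counts
        assert (c["concordant-up"], c["concordant-down"], c["discordant"]) == (4, 3, 3)
        assert sum(c.values()) == 10

    def test_swapping_treatments_preserves_discordant_count(self):
        rng = np.random.default_rng(3)
        ids = [f"P{i}" for i in range(50)]
        fc1 = rng.normal(size=50)
        fc2 = rng.normal(size=50)
        a = classify_concordance(
            fake_contrast(ids, fc1, "T1"), fake_contrast(ids, fc2, "T2"), ids
        )
        b = classify_concordance(
            fake_contrast(ids, fc2, "T2"), fake_contrast(ids, fc1, "T1"), ids
        )
        assert a.n_discordant == b.n_discordant
        assert a.counts["concordant-up"] == b.counts["concordant-up"]
        assert a.n_concordant == b.n_concordant

    def test_missing_protein_rejected(self):
        ids = ["P0", "P1"]
        res1 = fake_contrast(ids, [1, 2], "T1")
        res2 = fake_contrast(ids, [1, 2], "T2")
        with pytest.raises(ValueError, match="absent"):
            classify_concordance(res1, res2, ["P0", "P9"])
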