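import numpy as np
import pytest
from scipy import stats as sps

from lfqdelta import moderated_f, moderated_t, permutation_fdr
from lfqdelta.diffstats import (
    ddct_fold_change,
    holm_adjust,
    multi_group_anova,
    two_sample_contrast,
    volcano_boundary,
)

from conftest import make_design, make_quant, preprocessed_null


class TestModeratedT:
    def test_identical_groups_give_zero_statistic(self):
        delta, se, d, p = moderated_t([1, 1, 1], [1, 1, 1], s0=0.5)
        assert delta == 0 and d == 0
        assert p == 1.0

    def test_zero_variance_shift_forced_arithmetic(self):
        delta, se, d, p = moderated_t([0, 0, 0], [2, 2, 2], s0=0.5)
        assert se == 0
        assert d == pytest.approx(2 / 0.5)
        assert p == 0.0

    def test_s0_zero_reduces_to_classical_pooled_t(self):
        a, b = [0.0, -1.0, -2.0], [3.0, 2.0, 1.0]
        _, _, d, p = moderated_t(a, b, s0=0.0)
        ref = sps.ttest_ind(b, a, equal_var=True)
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(20, 3))
        B = rng.normal(size=(20, 4))
        delta, se, d, p = moderated_t(A, B, s0=0.3)
        for i in (0, 7, 19):
            di = moderated_t(A[i], B[i], s0=0.3)
            assert (delta[i], se[i], d[i], p[i]) == pytest.approx(di, abs=1e-12)

    def test_increasing_s0_never_increases_magnitude(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(100, 3))
        B = rng.normal(size=(100, 3))
        mags = []
        for s0 in (0.0, 0.25, 0.5, 1.0, 2.0):
            _, _, d, _ = moderated_t(A, B, s0=s0)
            mags.append(np.abs(d))
        for lo, hi in zip(mags[1:], mags[:-1]):
            assert np.all(lo <= hi + 1e-15)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            moderated_t([1.0], [2.0, 3.0], s0=0.5)

    def test_undefined_statistic_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            moderated_t([0, 0, 0], [2, 2, 2], s0=0.0)


class TestPermutationFdr:
    def test_dominant_protein_gets_q_zero(self):
        # one protein above every permuted value, 99 nulls
        rng = np.random.default_rng(0)
        obs = np.concatenate([[10.0], rng.uniform(0, 1, 99)])
        perm = rng.uniform(0, 2, size=(50, 100))
        q, c_star = permutation_fdr(obs, perm, q_star=0.05)
        assert q[0] == 0.0
        assert c_star <= 10.0

    def test_null_self_comparison_gives_all_q_one(self):
        obs = np.array([3.0, 2.0, 1.0])
        perm = np.tile(obs, (10, 1))
        q, c_star = permutation_fdr(obs, perm, q_star=0.05)
        np.testing.assert_array_equal(q, 1.0)
        assert np.isinf(c_star)

    def test_q_monotone_in_statistic_and_cutoff_consistent(self):
        rng = np.random.default_rng(3)
        obs = rng.exponential(size=200)
        perm = rng.exponential(size=(40, 200))
        q, c_star = permutation_fdr(obs, perm, q_star=0.05)
        order = np.argsort(-obs)
        assert np.all(np.diff(q[order]) >= -1e-15)
        np.testing.assert_array_equal(q <= 0.05, obs >= c_star)

    def test_ties_share_a_threshold(self):
        obs = np.array([2.0, 2.0, 1.0])
        perm = np.array([[0.5, 0.1, 0.2]])
        q, _ = permutation_fdr(obs, perm, 0.05)
        assert q[0] == q[1]

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            permutation_fdr([], np.empty((3, 0)), 0.05)


class TestTwoSampleContrast:
    def test_three_vs_three_triggers_exhaustive_enumeration(self, two_group_design):
        quant, design, _ = preprocessed_null(n_proteins=50, seed=1)
        res = two_sample_contrast(quant, design, "CTR", "T1", n_permutations=250)
        assert res.permutation_scheme == "exhaustive"
        # C(6,3)=20 distinct splits, minus the observed one and its mirror
        assert res.n_permutations == 18

    def test_monte_carlo_converges_to_enumeration(self):
        # 3-vs-3: MC q-values at B=10^4 agree with the exhaustive
        # enumeration oracle within 0.02 per protein
        quant, design, _ = preprocessed_null(n_proteins=60, seed=4)
        exact = two_sample_contrast(
            quant, design, "CTR", "T1", n_permutations=250, scheme="exhaustive"
        )
        mc = two_sample_contrast(
            quant, design, "CTR", "T1", n_permutations=10_000, seed=9,
            scheme="monte-carlo",
        )
        np.testing.assert_allclose(mc.q_value, exact.q_value, atol=0.02)

    def test_strong_signal_detected(self):
        # one protein shifted by 10 column-SDs among 200 nulls
        rng = np.random.default_rng(6)
        baseline = rng.normal(25, 2, size=201)
        values = baseline[:, None] + rng.normal(0, 0.3, size=(201, 6))
        col_sd = values.std(axis=0).mean()
        values[0, 3:] += 10 * col_sd
        quant = make_quant(
            values,
            sample_ids=["CTR_1", "CTR_2", "CTR_3", "T1_1", "T1_2", "T1_3"],
        ).advance("imputed", values)
        design = make_design({"CTR": 3, "T1": 3})
        res = two_sample_contrast(quant, design, "CTR", "T1")
        assert res.significant[0]
        assert res.log2_fc[0] > 0

    def test_missing_group_rejected(self, two_group_design):
        quant, design, _ = preprocessed_null(n_proteins=20, seed=2)
        with pytest.raises(ValueError, match="NOPE"):
            two_sample_contrast(quant, design, "CTR", "NOPE")


class TestMultiGroupAnova:
    def test_two_group_classical_f_equals_t_squared(self):
        quant, design, _ = preprocessed_null(n_proteins=80, seed=5)
        f_res = multi_group_anova(quant, design, s0_anova=0.0)
        a = design.column_indices(quant, "CTR")
        b = design.column_indices(quant, "T1")
        _, _, t, _ = moderated_t(quant.values[:, a], quant.values[:, b], s0=0.0)
        np.testing.assert_allclose(f_res.f_stat, t**2, atol=1e-10)

    def test_single_group_shift_detected(self):
        rng = np.random.default_rng(8)
        values = rng.normal(25, 0.3, size=(100, 9))
        values[0, 6:] += 6.0  # large shift in the third group only
        quant = make_quant(
            values,
            sample_ids=[f"{g}_{r}" for g in ("CTR", "IFNG", "IL27") for r in (1, 2, 3)],
        ).advance("imputed", values)
        design = make_design({"CTR": 3, "IFNG": 3, "IL27": 3})
        res = multi_group_anova(quant, design, n_permutations=250, seed=1)
        assert res.significant[0]

    def test_null_parametric_p_uniform(self):
        quant, design, _ = preprocessed_null(
            n_proteins=1000, groups={"A": 3, "B": 3, "C": 3}, seed=12
        )
        res = multi_group_anova(quant, design, n_permutations=100, seed=0)
        ks = sps.kstest(res.p_parametric, "uniform")
        assert ks.pvalue > 0.01
        assert res.n_significant / quant.n_proteins <= 0.05 + 0.01

    def test_single_sample_group_rejected(self):
        vals = np.random.default_rng(0).normal(size=(10, 4))
        quant = make_quant(vals, sample_ids=["A_1", "A_2", "A_3", "B_1"]).advance(
            "imputed", vals
        )
        with pytest.raises(ValueError, match=">=2"):
            multi_group_anova(quant, make_design({"A": 3, "B": 1}))


class TestHolmAdjust:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.2], [0.2]),
            ([0.01, 0.02, 0.9], [0.03, 0.04, 0.9]),
        ],
    )
    def test_hand_computed_fixtures(self, raw, expected):
        np.testing.assert_allclose(holm_adjust(raw), expected, atol=1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        ours = holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_dominates_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestVolcanoBoundary:
    def test_forced_arithmetic_point(self):
        pts = volcano_boundary(s0=0.5, cutoff=2.0, df=4, fc_grid=[2.0])
        fc, neglogp = pts[0]
        t_b = 2.0 * 2.0 / (2.0 - 1.0)
        assert fc == 2.0
        assert neglogp == pytest.approx(-np.log10(2 * sps.t.sf(t_b, 4)))

    def test_s0_zero_gives_flat_threshold(self):
        pts = volcano_boundary(s0=0.0, cutoff=2.0, df=4, fc_grid=[0.5, 1, 2, 8])
        np.testing.assert_allclose(pts[:, 1], pts[0, 1])

    def test_asymptote_approaches_cutoff(self):
        c, s0, df = 2.0, 0.5, 4
        pts = volcano_boundary(s0, c, df, fc_grid=[1e6])
        p_limit = -np.log10(2 * sps.t.sf(c, df))
        assert pts[0, 1] == pytest.approx(p_limit, rel=1e-4)

    def test_infeasible_fold_changes_excluded(self):
        pts = volcano_boundary(s0=0.5, cutoff=2.0, df=4, fc_grid=[0.5, 0.9, 1.5])
        # only fc > c*·s0 = 1 can reach the cutoff
        np.testing.assert_array_equal(pts[:, 0], [1.5])

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            volcano_boundary(0.5, 0.0, 4, [1.0])


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20, 20, 20, 20), 1.0),
            ((20, 19, 24, 22), 2.0),  # ddCt = -1
            ((20, 18, 24, 18), 16.0),  # ddCt = -4
        ],
    )
    def test_fold_change(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(20, np.nan, 24, 18)
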