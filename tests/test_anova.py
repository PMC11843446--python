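import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from enodal import (
    ExperimentDesign,
    OmicsMatrix,
    RunConfig,
    build_design_matrices,
    classify_features,
    fit_nested_models,
    hierarchical_adjust,
    lc_test,
    nested_f_test,
)
from enodal.anova import MODEL_NAMES
from enodal.simulate import SimulationSpec, simulate_design


def _design(n=50, L=4, K=4, seed=0, collinear=False):
    rng = np.random.default_rng(seed)
    W = rng.normal(0, 1, (n, L))
    if collinear:
        W[:, -1] = W[:, :-1].sum(axis=1)  # energy = protein + carb + fat
    levels = [f"t{k}" for k in range(K)]
    D = np.array([levels[i % K] for i in range(n)], dtype=object)
    return ExperimentDesign([f"s{i}" for i in range(n)], W, D, "t0")


class TestDesignMatrices:
    def test_full_rank_column_counts(self):
        m = build_design_matrices(_design(n=80, L=4, K=4))
        assert [m[x].rank for x in ("M5", "M4", "M3", "M2", "M1")] == [1, 5, 4, 8, 20]

    def test_k2_l1_interaction_model(self):
        m = build_design_matrices(_design(n=20, L=1, K=2))
        assert m["M1"].rank == 4

    def test_exact_collinear_column_dropped_and_recorded(self):
        m = build_design_matrices(_design(n=80, collinear=True))
        assert m["M4"].rank == 4
        assert len(m["M4"].dropped) == 1
        # nesting of kept columns survives the drop
        assert set(m["M4"].columns) <= set(m["M2"].columns) <= set(m["M1"].columns)

    def test_residual_df_strictly_decrease_to_m1(self):
        m = build_design_matrices(_design(n=80))
        dfs = [m[x].df_resid for x in ("M5", "M4", "M3", "M2", "M1")]
        assert dfs[0] > dfs[1] > dfs[3] > dfs[4] and dfs[0] > dfs[2] > dfs[3]


class TestFitNestedModels:
    def test_constant_feature_has_zero_rss_everywhere(self):
        m = build_design_matrices(_design())
        fits = fit_nested_models(m, np.full(50, 3.7))
        assert all(abs(fits.rss[name]) < 1e-18 for name in MODEL_NAMES)

    def test_noiseless_nutrition_signal_nests(self):
        d = _design(n=60)
        m = build_design_matrices(d)
        z = 2.0 + d.W @ np.array([1.0, -0.5, 0.3, 0.0])
        fits = fit_nested_models(m, z)
        assert fits.rss["M4"] < 1e-16 and fits.rss["M1"] < 1e-16
        assert fits.rss["M5"] > 1.0

    def test_rss_monotone_over_nesting(self):
        d = _design(n=50, seed=3)
        m = build_design_matrices(d)
        rng = np.random.default_rng(8)
        for _ in range(10):
            fits = fit_nested_models(m, rng.normal(0, 1, 50))
            r = fits.rss
            assert r["M1"] <= r["M2"] + 1e-9
            assert r["M2"] <= min(r["M3"], r["M4"]) + 1e-9
            assert r["M5"] >= max(r["M3"], r["M4"]) - 1e-9

    def test_coefficients_match_pseudoinverse_oracle(self):
        d = _design(n=50, seed=1)
        m = build_design_matrices(d)
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, 50)
        fits = fit_nested_models(m, z)
        for name in MODEL_NAMES:
            oracle = np.linalg.pinv(m[name].X) @ z
            got = np.array([fits.coef[name][c] for c in m[name].columns])
            np.testing.assert_allclose(got, oracle, atol=1e-8)


class TestNestedFTest:
    def test_equal_rss_gives_p_one(self):
        F, p = nested_f_test(5.0, 40, 5.0, 30)
        assert (F, p) == (0.0, 1.0)

    def test_zero_full_rss_degenerate(self):
        assert nested_f_test(1.0, 40, 0.0, 30)[1] == 0.0
        assert nested_f_test(0.0, 40, 0.0, 30)[1] == 1.0

    def test_interaction_delta_df(self):
        m = build_design_matrices(_design(n=80, L=4, K=4))
        assert m["M2"].df_resid - m["M1"].df_resid == 12  # L(K-1)

    def test_matches_statsmodels_oracle(self):
        """Dual route: our extra-sum-of-squares F vs statsmodels compare_f_test."""
        d = _design(n=60, seed=5)
        m = build_design_matrices(d)
        rng = np.random.default_rng(11)
        for _ in range(100):
            z = rng.normal(0, 1, 60) + d.W @ rng.normal(0, 0.3, 4)
            fits = fit_nested_models(m, z)
            _, p = nested_f_test(fits.rss["M2"], fits.df_resid["M2"],
                                 fits.rss["M1"], fits.df_resid["M1"])
            full = sm.OLS(z, m["M1"].X).fit()
            null = sm.OLS(z, m["M2"].X).fit()
            _, p_oracle, _ = full.compare_f_test(null)
            assert abs(p - p_oracle) < 1e-10


class TestLCTest:
    def test_p_value_bounds(self):
        d = _design(n=40)
        m = build_design_matrices(d)
        rng = np.random.default_rng(0)
        for j in range(5):
            p = lc_test(m, rng.normal(0, 1, 40), B=99, seed=0, feature_index=j)
            assert 1 / 100 <= p <= 1.0

    def test_zero_variance_gives_p_one(self):
        m = build_design_matrices(_design(n=40))
        assert lc_test(m, np.zeros(40), B=99, seed=0) == 1.0

    def test_null_rejection_rate_near_alpha(self):
        """Unadjusted level of the permutation test under i.i.d. noise."""
        d = _design(n=40, seed=2)
        m = build_design_matrices(d)
        rng = np.random.default_rng(3)
        pvals = np.array([
            lc_test(m, rng.normal(0, 1, 40), B=199, seed=17, feature_index=j)
            for j in range(500)
        ])
        rate = np.mean(pvals <= 0.05)
        assert abs(rate - 0.05) < 0.03

    def test_strong_interaction_hits_permutation_floor(self):
        spec = SimulationSpec(seed=4)
        d = simulate_design(spec)
        m = build_design_matrices(d)
        rng = np.random.default_rng(5)
        Ws = (d.W - d.W.mean(0)) / d.W.std(0)
        sign = np.where(d.D == "control", 1.0, -3.0)
        z = sign * Ws[:, 0] * 3 + rng.normal(0, 1, d.n)
        assert lc_test(m, z, B=500, seed=1) == 1 / 501

    def test_invariant_to_joint_sample_reordering(self):
        d = _design(n=40, seed=6)
        rng = np.random.default_rng(7)
        z = rng.normal(0, 1, 40)
        perm = rng.permutation(40)
        d2 = ExperimentDesign([d.sample_ids[i] for i in perm], d.W[perm],
                              d.D[perm], d.control_level)
        p1 = lc_test(build_design_matrices(d), z, B=199, seed=9)
        p2 = lc_test(build_design_matrices(d2), z[perm], B=199, seed=9)
        assert p1 == p2


class TestHierarchicalAdjust:
    @pytest.mark.parametrize(
        "p,n,expected_adj,expected_reject",
        [(0.0004, 100, 0.04, True), (0.001, 200, 0.2, False), (0.02, 1, 0.02, True)],
    )
    def test_bonferroni_layer(self, p, n, expected_adj, expected_reject):
        adj, rej = hierarchical_adjust(np.array([p]), n, 0.05)
        assert adj[0] == pytest.approx(expected_adj)
        assert rej[0] == expected_reject

    def test_bh_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        adj, _ = hierarchical_adjust(p, 50, 0.05, method="bh")
        assert np.all(adj >= p - 1e-15)


class TestClassifyFeatures:
    def test_labels_partition_features(self, factorial_dataset, fast_config):
        design, omics, truth, _ = factorial_dataset
        asg = classify_features(omics, design, fast_config)
        assert len(asg.labels) == omics.p
        assert set(asg.labels) <= {"NxD", "N+D", "N", "D", "nonsig"}

    def test_single_feature_equals_manual_cascade(self):
        """classify_features on one feature reproduces the three tests run by hand."""
        spec = SimulationSpec(seed=9)
        d = simulate_design(spec)
        m = build_design_matrices(d)
        rng = np.random.default_rng(10)
        Ws = (d.W - d.W.mean(0)) / d.W.std(0)
        z = Ws @ np.array([1.0, -1, 0.5, 0]) + rng.normal(0, 1, d.n)
        cfg = RunConfig(n_permutations=199, seed=21)
        asg = classify_features(OmicsMatrix(["f"], z[None, :]), d, cfg)
        p_hand = lc_test(m, z, B=199, seed=21, feature_index=0)
        assert asg.p_global[0] == p_hand
        fits = fit_nested_models(m, z)
        _, p_int = nested_f_test(fits.rss["M2"], fits.df_resid["M2"],
                                 fits.rss["M1"], fits.df_resid["M1"])
        assert asg.p_interaction[0] == pytest.approx(p_int, abs=1e-12)

    def test_interaction_null_block_not_labelled_interactive(self):
        """Features generated from the additive model keep gamma out of their label."""
        spec = SimulationSpec(feature_counts={"M2": 60}, seed=13, gamma_scale=0.0)
        d = simulate_design(spec)
        from enodal.simulate import simulate_omics

        omics, truth = simulate_omics(d, spec)
        cfg = RunConfig(n_permutations=1499, seed=3)
        asg = classify_features(omics, d, cfg)
        assert np.mean(asg.labels == "NxD") <= 0.05

    def test_too_small_sample_all_untestable(self, caplog):
        rng = np.random.default_rng(0)
        n, L = 10, 4
        W = rng.normal(0, 1, (n, L))
        D = np.array(["a", "b", "c", "d", "e"] * 2, dtype=object)
        d = ExperimentDesign([f"s{i}" for i in range(n)], W, D, "a")
        omics = OmicsMatrix(["f1"], rng.normal(0, 1, (1, n)))
        asg = classify_features(omics, d, RunConfig(n_permutations=99, seed=0))
        assert list(asg.labels) == ["nonsig"]
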