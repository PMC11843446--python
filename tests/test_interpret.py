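import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enodal import (
    ExperimentDesign,
    OmicsMatrix,
    RunConfig,
    annotate_subcluster,
    compute_interpretable_features,
    correlation_shift,
    fisher_z,
    pairwise_t,
    ternarize,
)
from enodal.interpret import InterpretableFeatures


def _atanh_series(r, tol=1e-16):
    """Independent arctanh evaluation by power series."""
    total, term, k = 0.0, r, 0
    while abs(term) / (2 * k + 1) > tol:
        total += term / (2 * k + 1)
        k += 1
        term *= r * r
    return total


class TestFisherZ:
    def test_zero_correlation_is_zero(self):
        assert fisher_z(0.0, 30) == 0.0

    @given(st.floats(-0.98, 0.98), st.integers(5, 200))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry(self, r, n):
        assert fisher_z(-r, n) == pytest.approx(-fisher_z(r, n), abs=1e-12)

    def test_matches_series_oracle_on_grid(self):
        for r in np.linspace(-0.99, 0.99, 41):
            for n in (5, 12, 28, 100, 200):
                expected = np.sqrt(n - 3) * _atanh_series(float(r))
                assert fisher_z(float(r), n) == pytest.approx(expected, abs=1e-12)

    def test_half_correlation_n28(self):
        assert fisher_z(0.5, 28) == pytest.approx(5 * np.arctanh(0.5), abs=1e-12)

    def test_perfect_correlation_clamped(self):
        assert fisher_z(1.0, 30) == pytest.approx(np.sqrt(27) * 38.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(0.5, 3)

    def test_literal_scale_option(self):
        assert fisher_z(0.5, 28, literal_scale=True) == pytest.approx(np.arctanh(0.5) / 5)


class TestPairwiseT:
    def test_identical_groups_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pairwise_t(x, x.copy()) == 0.0

    def test_swap_negates(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        assert pairwise_t(a, b) == pytest.approx(-pairwise_t(b, a), abs=1e-14)

    def test_hand_computed_value(self):
        # groups with mean 2 vs 1 and sample variance 1, n = 4 each:
        # t = (2 - 1) / sqrt(1/4 + 1/4) = sqrt(2) ~ 1.4142
        a = np.array([2.0, 2.0, 2.0 - np.sqrt(1.5), 2.0 + np.sqrt(1.5)])
        b = a - 1.0
        assert a.var(ddof=1) == pytest.approx(1.0)
        assert pairwise_t(a, b) == pytest.approx(np.sqrt(2), abs=1e-12)
        assert pairwise_t(a, b) == pytest.approx(1.4142, abs=1e-4)


class TestCorrelationShift:
    def test_equal_correlations_give_zero(self):
        assert correlation_shift(0.4, 20, 0.4, 25) == 0.0

    def test_swap_negates(self):
        assert correlation_shift(0.6, 23, 0.1, 30) == pytest.approx(
            -correlation_shift(0.1, 30, 0.6, 23), abs=1e-14
        )

    def test_closed_form_oracle(self):
        got = correlation_shift(0.6, 23, 0.0, 23)
        assert got == pytest.approx(_atanh_series(0.6) / np.sqrt(2 / 20), abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            correlation_shift(0.5, 3, 0.5, 20)


class TestTernarize:
    @pytest.mark.parametrize("stat,expected", [(2.0, 1), (0.0, 0), (-1.7, -1),
                                               (1.6448, 0), (1.645, 1)])
    def test_default_threshold(self, stat, expected):
        assert ternarize(stat) == expected

    def test_missing_stays_missing(self):
        assert np.isnan(ternarize(np.nan))


def _features_with_set3(values_per_member, L=1, K=2):
    """Build an InterpretableFeatures with a single set-3 cell per member."""
    p = len(values_per_member)
    ids = [f"f{i}" for i in range(p)]
    return InterpretableFeatures(
        ids, ["carb"], ["rapamycin"],
        set1=np.zeros((p, 1)), set2=np.zeros((p, 1)),
        set3=np.array(values_per_member, dtype=float).reshape(p, 1, 1),
    ), ids


class TestAnnotateSubcluster:
    def test_eight_of_ten_emits_record(self):
        feats, ids = _features_with_set3([2.0] * 8 + [0.0] * 2)
        ann = annotate_subcluster(ids, feats)
        assert len(ann.records) == 1
        rec = ann.records[0]
        assert (rec.statistic_set, rec.nutrition, rec.treatment) == ("set3", "carb", "rapamycin")
        assert rec.direction == "increased" and rec.proportion == pytest.approx(0.8)

    def test_seven_of_ten_is_below_strict_threshold(self):
        feats, ids = _features_with_set3([2.0] * 7 + [0.0] * 3)
        assert annotate_subcluster(ids, feats).records == []

    def test_all_zero_statistics_give_empty_annotation(self):
        feats, ids = _features_with_set3([0.0] * 10)
        assert annotate_subcluster(ids, feats).records == []

    def test_missing_values_count_in_denominator_only(self):
        feats, ids = _features_with_set3([2.0] * 7 + [np.nan] * 3)
        assert annotate_subcluster(ids, feats).records == []
        feats, ids = _features_with_set3([2.0] * 8 + [np.nan] * 2)
        assert len(annotate_subcluster(ids, feats).records) == 1

    def test_invariant_to_member_order(self):
        feats, ids = _features_with_set3([2.0] * 8 + [-2.0, 0.0])
        a = annotate_subcluster(ids, feats)
        b = annotate_subcluster(ids[::-1], feats)
        assert [(r.statistic_set, r.direction, r.proportion) for r in a.records] == \
               [(r.statistic_set, r.direction, r.proportion) for r in b.records]


@pytest.fixture(scope="module")
def computed():
    rng = np.random.default_rng(12)
    n = 40
    W = rng.normal(0, 1, (n, 2))
    D = np.array((["ctrl"] * 10 + ["a"] * 10 + ["b"] * 10 + ["c"] * 10), dtype=object)
    design = ExperimentDesign([f"s{i}" for i in range(n)], W, D, "ctrl",
                              ["protein", "carb"])
    Z = np.vstack([
        2 * W[:, 0] + rng.normal(0, 0.5, n),          # nutrition-linked
        np.where(D == "a", 3.0, 0.0) + rng.normal(0, 0.5, n),  # drug-a shifted
    ])
    omics = OmicsMatrix(["f_nut", "f_drug"], Z)
    return design, omics, compute_interpretable_features(omics, design)


class TestComputeInterpretableFeatures:
    def test_shapes(self, computed):
        design, omics, feats = computed
        assert feats.set1.shape == (2, 2)
        assert feats.set2.shape == (2, 3)
        assert feats.set3.shape == (2, 2, 3)

    def test_planted_signals_show_in_expected_cells(self, computed):
        _, _, feats = computed
        assert feats.set1[0, 0] > 3          # strong positive overall correlation
        assert feats.set2[1, 0] > 3          # drug-a up-shift, first non-control level
        assert abs(feats.set2[1, 1]) < 2.5   # other drugs unshifted

    def test_sign_flip_of_nutrition_column_flips_set1_and_set3(self, computed):
        design, omics, feats = computed
        W2 = design.W.copy()
        W2[:, 0] *= -1
        design2 = ExperimentDesign(design.sample_ids, W2, design.D,
                                   design.control_level, design.nutrition_names)
        feats2 = compute_interpretable_features(omics, design2)
        np.testing.assert_allclose(feats2.set1[:, 0], -feats.set1[:, 0], atol=1e-10)
        np.testing.assert_allclose(feats2.set3[:, 0, :], -feats.set3[:, 0, :], atol=1e-10)
        np.testing.assert_allclose(feats2.set2, feats.set2, atol=1e-12)

    def test_proportion_sum_bounded(self, computed):
        _, _, feats = computed
        from enodal.interpret import _proportions, ternarize as tern

        vals = np.vectorize(lambda v: tern(v, 0.95))(feats.set1[:, 0])
        P, N = _proportions(vals)
        assert P + N <= 1.0
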