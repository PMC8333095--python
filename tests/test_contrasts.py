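import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_step_up
from platelet_landscape import contrasts, preprocess
from platelet_landscape.io_tables import ValidationError
from platelet_landscape.preprocess import NormalizedMatrix
from platelet_landscape.synthetic_cohort import CohortConfig, generate_cohort


class TestFoldChange:
    def test_ratio_of_linear_means(self, toy_norm, toy_groups):
        fc = contrasts.fold_change(toy_norm, toy_groups, "two", "one")
        assert fc["gA"] == pytest.approx(4.0)  # 64 vs 16
        assert fc["gB"] == pytest.approx(1.0)

    def test_identical_groups_give_unit_fc(self, toy_norm, toy_groups):
        # gB and gC have the same value multiset in both groups
        fc = contrasts.fold_change(toy_norm, toy_groups, "one", "two")
        np.testing.assert_allclose(fc["gB"], 1.0)
        np.testing.assert_allclose(fc["gC"], 1.0)

    def test_swap_gives_reciprocal(self, toy_norm, toy_groups):
        ab = contrasts.fold_change(toy_norm, toy_groups, "one", "two")
        ba = contrasts.fold_change(toy_norm, toy_groups, "two", "one")
        np.testing.assert_allclose(ab.to_numpy() * ba.to_numpy(), 1.0)

    def test_zero_denominator_flags_infinity(self):
        vals = np.array([[0.0, 0.0, 3.0, 3.0]])
        norm = NormalizedMatrix(["g"], ["a1", "a2", "b1", "b2"], vals, np.ones(4))
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        fc = contrasts.fold_change(norm, groups, "B", "A")
        assert np.isinf(fc["g"])

    def test_log_mode_uses_mean_of_log_scale(self, toy_norm, toy_groups):
        fc = contrasts.fold_change(toy_norm, toy_groups, "two", "one", mode="log")
        # gA: stored values are log2(16+1) and log2(64+1), so the log-scale
        # ratio is 65/17 rather than the linearized 64/16
        assert fc["gA"] == pytest.approx(65 / 17)
        assert fc["gA"] != pytest.approx(4.0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(contrasts.bh_adjust([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            contrasts.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            contrasts.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=100)
    def test_dominates_input_and_matches_brute_force(self, p):
        q = contrasts.bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()
        np.testing.assert_allclose(q, bh_step_up(np.asarray(p)), atol=1e-12)


class TestGroupTtest:
    def test_identical_groups_degenerate_p_one(self):
        vals = np.array([[5.0, 6.0, 5.0, 6.0]])
        norm = NormalizedMatrix(["g"], ["a1", "a2", "b1", "b2"], vals, np.ones(4))
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        # both groups hold the same values (5, 6): Welch t = 0, p = 1
        out = contrasts.group_ttest(norm, groups, "A", "B")
        assert out.loc["g", "p_value"] == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        vals = np.array([[5.0, 5.0, 5.0, 5.0]])
        norm = NormalizedMatrix(["g"], ["a1", "a2", "b1", "b2"], vals, np.ones(4))
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        out = contrasts.group_ttest(norm, groups, "A", "B")
        assert out.loc["g", "p_value"] == 1.0
        assert out.loc["g", "q_value"] == 1.0
        assert out.loc["g", "flag"] == "degenerate_equal"

    def test_zero_variance_unequal_means_flagged(self):
        vals = np.array([[5.0, 5.0, 7.0, 7.0]])
        norm = NormalizedMatrix(["g"], ["a1", "a2", "b1", "b2"], vals, np.ones(4))
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        out = contrasts.group_ttest(norm, groups, "A", "B")
        assert out.loc["g", "p_value"] == 0.0
        assert out.loc["g", "flag"] == "degenerate_unequal"

    def test_singleton_group_rejected(self, toy_norm):
        groups = pd.Series({"s1": "A", "s2": "B", "s3": "B", "s4": "B"})
        with pytest.raises(ValidationError):
            contrasts.group_ttest(toy_norm, groups, "A", "B")

    def test_q_values_monotone_in_p_rank(self, small_cohort):
        counts, samples, _ = small_cohort
        groups = samples.set_index("sample_id")["sex"]
        norm = preprocess.preprocess_counts(counts, groups)
        out = contrasts.group_ttest(norm, groups, "male", "female")
        by_p = out.sort_values("p_value")
        assert (np.diff(by_p["q_value"]) >= -1e-12).all()


class TestAgeCorrelation:
    @staticmethod
    def _norm_from(values):
        values = np.asarray(values, dtype=float)
        return NormalizedMatrix(
            [f"g{i}" for i in range(values.shape[0])],
            [f"s{i}" for i in range(values.shape[1])],
            values,
            np.ones(values.shape[1]),
        )

    def test_perfect_linearity(self):
        ages = np.array([20.0, 30.0, 40.0, 55.0])
        norm = self._norm_from([ages, -ages])
        out = contrasts.age_correlation(norm, ages)
        assert out.loc["g0", "r"] == pytest.approx(1.0)
        assert out.loc["g1", "r"] == pytest.approx(-1.0)
        assert out.loc["g0", "p_value"] == 0.0

    def test_constant_gene_flagged_missing_not_zero(self):
        ages = np.array([20.0, 30.0, 40.0, 55.0])
        norm = self._norm_from([[5.0] * 4, ages])
        out = contrasts.age_correlation(norm, ages)
        assert out.loc["g0", "missing"]
        assert np.isnan(out.loc["g0", "r"])
        # constant gene excluded from the BH family: remaining q == p
        assert out.loc["g1", "q_value"] == pytest.approx(out.loc["g1", "p_value"])

    def test_notable_band_is_open_at_03(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(20, 80, 40)
        noise = rng.normal(size=40)
        norm = self._norm_from([0.02 * ages + noise * 5.0, 0.5 * ages + noise])
        out = contrasts.age_correlation(norm, ages)
        assert bool(out["notable"].iloc[1])
        assert abs(out["r"].iloc[0]) < 0.3 and not bool(out["notable"].iloc[0])

    def test_matches_scipy_pearsonr(self, small_cohort):
        from scipy import stats

        counts, samples, _ = small_cohort
        groups = samples.set_index("sample_id")["sex"]
        norm = preprocess.preprocess_counts(counts, groups)
        ages = samples.set_index("sample_id")["age_years"]
        out = contrasts.age_correlation(norm, ages)
        for gi in [0, 7, 42]:
            r, p = stats.pearsonr(norm.values[gi], ages.loc[list(norm.sample_ids)])
            assert out["r"].iloc[gi] == pytest.approx(r, abs=1e-12)
            assert out["p_value"].iloc[gi] == pytest.approx(p, rel=1e-9)


class TestTopNOverlap:
    def test_identity_disjoint_and_partial(self):
        a = ["g1", "g2", "g3", "g4"]
        b = ["g3", "g4", "g5", "g6"]
        assert contrasts.top_n_overlap(a, a, 4) == 1.0
        assert contrasts.top_n_overlap(a, ["x1", "x2", "x3", "x4"], 4) == 0.0
        assert contrasts.top_n_overlap(a, b, 4) == 0.5

    def test_n_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            contrasts.top_n_overlap(["g1"], ["g1"], 2)


def test_ttest_type_one_error_calibrated_on_null_cohort():
    """Welch t-test per-gene false positive rate near nominal on null data."""
    counts, samples, _ = generate_cohort(
        CohortConfig.null(n_samples=40, n_genes=2000, seed=5)
    )
    groups = samples.set_index("sample_id")["sex"]
    norm = preprocess.preprocess_counts(counts, groups)
    out = contrasts.group_ttest(norm, groups, "female", "male")
    assert 0.04 <= (out["p_value"] < 0.05).mean() <= 0.06
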