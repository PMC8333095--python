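import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from oracles import min_spanning_tree_weight, similarity_diff, similarity_exact_p
from platelet_landscape import preprocess, vector_stats as vs
from platelet_landscape.io_tables import ValidationError
from platelet_landscape.preprocess import NormalizedMatrix
from platelet_landscape.synthetic_cohort import CohortConfig, generate_cohort


def _dist_1d(points):
    x = np.asarray(points, dtype=float)
    return np.abs(x[:, None] - x[None, :])


PATH4 = _dist_1d([0.0, 1.0, 2.0, 3.0])
IDS4 = ["s1", "s2", "s3", "s4"]


class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        norm = NormalizedMatrix(
            ["g1", "g2"], ["a", "b"], np.array([[0.0, 3.0], [0.0, 4.0]]), np.ones(2)
        )
        d = vs.euclidean_distance_matrix(norm)
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "a"] == 0.0

    def test_matches_from_definition_computation(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 4))
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(5)],
            [f"s{i}" for i in range(4)],
            vals,
            np.ones(4),
        )
        d = vs.euclidean_distance_matrix(norm).to_numpy()
        for i in range(4):
            for j in range(4):
                expected = np.sqrt(((vals[:, i] - vals[:, j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected)


class TestMinimumSpanningTree:
    def test_collinear_points_give_path(self):
        mst = vs.minimum_spanning_tree(_dist_1d([0.0, 1.0, 3.0]))
        assert mst.edges.tolist() == [[0, 1], [1, 2]]
        assert mst.total_weight == pytest.approx(3.0)

    def test_two_nodes_forced_edge(self):
        mst = vs.minimum_spanning_tree(_dist_1d([0.0, 7.0]))
        assert mst.edges.tolist() == [[0, 1]]
        assert mst.total_weight == 7.0

    def test_weight_optimal_vs_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            d = squareform(pdist(rng.normal(size=(n, 3))))
            mst = vs.minimum_spanning_tree(d)
            assert mst.total_weight == pytest.approx(
                min_spanning_tree_weight(d), abs=1e-9
            )


class TestWwRunsTest:
    def test_path_fixture_statistic_and_exact_p(self):
        res = vs.ww_runs_test(PATH4, ["A", "A", "B", "B"], sample_ids=IDS4)
        assert res.statistic == 2.0
        assert res.exact and res.n_perm == 6
        assert res.p_value == pytest.approx(2 / 6)

    def test_alternating_labels_give_max_runs(self):
        res = vs.ww_runs_test(PATH4, ["A", "B", "A", "B"], sample_ids=IDS4)
        assert res.statistic == 4.0

    def test_separated_clouds_hit_permutation_floor(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (10, 5)), rng.normal(30, 1, (10, 5))])
        d = squareform(pdist(pts))
        labels = ["A"] * 10 + ["B"] * 10
        res = vs.ww_runs_test(
            d, labels, n_perm=99, seed=1, sample_ids=[f"s{i:02d}" for i in range(20)]
        )
        assert res.p_value == pytest.approx(1 / 100)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            vs.ww_runs_test(PATH4, ["A", "B", "B", "B"], sample_ids=IDS4)


class TestKsMstTest:
    def test_path_fixture_statistic_and_exact_p(self):
        res = vs.ks_mst_test(PATH4, ["A", "A", "B", "B"], sample_ids=IDS4)
        assert res.statistic == pytest.approx(1.0)
        assert res.exact
        assert res.p_value == pytest.approx(2 / 6)

    def test_alternating_labels_halve_discrepancy(self):
        res = vs.ks_mst_test(PATH4, ["A", "B", "A", "B"], sample_ids=IDS4)
        assert res.statistic == pytest.approx(0.5)

    def test_ranking_is_path_order_from_an_end(self):
        mst = vs.minimum_spanning_tree(PATH4)
        assert vs.mst_ks_ranking(mst).tolist() == [0, 1, 2, 3]

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        labels = ["A"] * 8 + ["B"] * 8
        for i in range(120):
            d = squareform(pdist(rng.normal(size=(16, 10))))
            res = vs.ks_mst_test(
                d, labels, n_perm=99, seed=i, sample_ids=[f"s{j:02d}" for j in range(16)]
            )
            ps.append(res.p_value)
        ps = np.array(ps)
        # discrete and conservative, but the bulk must not concentrate
        assert 0.35 <= ps.mean() <= 0.75
        assert (ps <= 0.25).mean() <= 0.35


class TestGroupSimilarity:
    def test_median_of_three_reciprocals(self):
        d = np.array([[0, 1, 2], [1, 0, 4], [2, 4, 0]], dtype=float)
        assert vs.group_similarity(d, [0, 1, 2]) == pytest.approx(0.5)

    def test_single_pair(self):
        assert vs.group_similarity(_dist_1d([0.0, 2.0]), [0, 1]) == pytest.approx(0.5)

    def test_homogeneity_under_distance_scaling(self):
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.normal(size=(6, 3))))
        s1 = vs.group_similarity(d, [0, 2, 4])
        s3 = vs.group_similarity(3.0 * d, [0, 2, 4])
        assert s3 == pytest.approx(s1 / 3.0)

    def test_duplicate_vectors_error_names_pair(self):
        d = _dist_1d([1.0, 1.0, 5.0])
        with pytest.raises(ValidationError, match="'0'.*'1'"):
            vs.group_similarity(d, [0, 1, 2])


class TestSimilarityPermutationTest:
    def test_matches_exhaustive_oracle_on_six_points(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.normal(size=(6, 2))))
        in_a = np.array([True, True, True, False, False, False])
        res = vs.similarity_permutation_test(
            d, ["A", "A", "A", "B", "B", "B"], sample_ids=[f"s{i}" for i in range(6)]
        )
        assert res.exact and res.n_perm == 20
        assert res.observed_diff == pytest.approx(similarity_diff(d, in_a))
        assert res.p_value == pytest.approx(similarity_exact_p(d, in_a))

    def test_zero_observed_diff_gives_p_one(self):
        # symmetric configuration: two congruent groups -> diff exactly 0
        x = np.array([0.0, 1.0, 3.0, 10.0, 11.0, 13.0])
        d = _dist_1d(x)
        res = vs.similarity_permutation_test(
            d, ["A", "A", "A", "B", "B", "B"], sample_ids=[f"s{i}" for i in range(6)]
        )
        assert res.observed_diff == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_default_n_perm_is_ten_thousand(self):
        import inspect

        sig = inspect.signature(vs.similarity_permutation_test)
        assert sig.parameters["n_perm"].default == 10_000

    def test_label_swap_negates_diff_and_keeps_p(self):
        rng = np.random.default_rng(12)
        d = squareform(pdist(rng.normal(size=(12, 4))))
        ids = [f"s{i:02d}" for i in range(12)]
        lab = ["A"] * 6 + ["B"] * 6
        swapped = ["B" if l == "A" else "A" for l in lab]
        r1 = vs.similarity_permutation_test(d, lab, n_perm=99, seed=4, sample_ids=ids)
        r2 = vs.similarity_permutation_test(d, swapped, n_perm=99, seed=4, sample_ids=ids)
        assert r2.observed_diff == pytest.approx(-r1.observed_diff)
        assert r2.p_value == r1.p_value


class TestPermutationInvariances:
    def test_p_values_invariant_to_sample_order(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(14, 5))
        d = squareform(pdist(pts))
        ids = [f"s{i:02d}" for i in range(14)]
        lab = pd.Series(["A"] * 7 + ["B"] * 7, index=ids)
        perm = rng.permutation(14)
        d2 = d[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        for fn in (vs.ks_mst_test, vs.ww_runs_test, vs.similarity_permutation_test):
            r1 = fn(d, lab, n_perm=99, seed=5, sample_ids=ids)
            r2 = fn(d2, lab, n_perm=99, seed=5, sample_ids=ids2)
            assert r1.p_value == r2.p_value

    def test_exact_p_has_floor_one_over_labelings(self):
        res = vs.ww_runs_test(PATH4, ["A", "A", "B", "B"], sample_ids=IDS4)
        assert res.p_value >= 1 / res.n_perm


class TestAdjustAlpha:
    def test_table_footnote_thresholds(self):
        assert f"{vs.adjust_alpha(0.05, 3):.4f}" == "0.0167"
        assert f"{vs.adjust_alpha(0.05, 1):.4f}" == "0.0500"
        assert vs.adjust_alpha(0.05, 10) == pytest.approx(0.005)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            vs.adjust_alpha(0.05, 0)


@pytest.fixture(scope="module")
def null_battery():
    counts, samples, _ = generate_cohort(CohortConfig.null(n_samples=48, seed=3))
    norm = preprocess.preprocess_counts(
        counts, samples.set_index("sample_id")["sex"]
    )
    return vs.run_table1_battery(norm, samples, n_perm=99, seed=9)


class TestBattery:
    def test_three_libsize_pairs_at_bonferroni_third(self, null_battery):
        lib = null_battery[null_battery["factor"] == "libsize_batch"]
        assert len(lib) == 3
        assert set(lib["comparison"]) == {"1 vs 2", "1 vs 3", "2 vs 3"}
        np.testing.assert_allclose(lib["threshold"], 0.05 / 3)

    def test_other_factors_at_plain_alpha(self, null_battery):
        other = null_battery[null_battery["factor"] != "libsize_batch"]
        np.testing.assert_allclose(other["threshold"], 0.05)

    def test_null_cohort_mostly_not_significant(self, null_battery):
        sig = null_battery[["sig_ks", "sig_ww", "sig_similarity"]].to_numpy()
        assert sig.mean() <= 0.15

    def test_planted_cluster_comparison_is_detected(self, small_cohort):
        counts, samples, truth = small_cohort
        norm = preprocess.preprocess_counts(
            counts, samples.set_index("sample_id")["sex"]
        )
        table = vs.run_table1_battery(
            norm, samples, cluster=truth.cluster_labels, n_perm=199, seed=2
        )
        row = table[table["factor"] == "cluster"].iloc[0]
        assert row["p_ks"] <= 0.05
        assert row["p_ww"] <= 0.05
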