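"""2-D reduction, two-level k-means, pooled variance, Moran's I."""

import numpy as np
import pytest

from cdr3vec.errors import NoNeighborsError, UndefinedVarianceError, ZeroVarianceError
from cdr3vec.wordlevel import (
    ClusterSet,
    distance_distribution_test,
    homogeneity_report,
    kmeans_two_level,
    morans_i,
    morans_profile,
    pooled_variance,
    reduce_2d,
)


def brute_force_morans_i(points, values, d_x):
    """Independent O(n^2) double-loop evaluation of the Moran's I equation."""
    n = len(points)
    z = np.asarray(values, float) - np.mean(values)
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(points[i] - points[j])))
            if 0 < d < d_x:
                num += z[i] * z[j]
                s0 += 1
    return (n / s0) * num / float(z @ z)


class TestReduce2D:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 10))
        a = reduce_2d(X, seed=5)
        b = reduce_2d(X, seed=5)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, b)

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            reduce_2d(np.ones((1, 5)))


class TestTwoLevelKMeans:
    def test_square_bookkeeping(self):
        rng = np.random.default_rng(1)
        points = rng.uniform(size=(800, 2))
        cs = kmeans_two_level(points, 8, 5, seed=0)
        assert cs.k == 40
        sizes = [len(v) for v in cs.groups().values()]
        assert sum(sizes) == 800
        assert np.mean(sizes) == pytest.approx(800 / 40)

    def test_single_cluster(self):
        points = np.random.default_rng(2).uniform(size=(10, 2))
        cs = kmeans_two_level(points, 1, 1, seed=0)
        assert cs.k == 1 and len(cs.members_of(0)) == 10

    def test_ids_dense(self):
        points = np.random.default_rng(3).uniform(size=(100, 2))
        cs = kmeans_two_level(points, 4, 4, seed=0)
        assert sorted(set(cs.assignment.values())) == list(range(cs.k))


class TestPooledVariance:
    def test_single_cluster_equals_overall_variance(self):
        rng = np.random.default_rng(4)
        vals = {i: v for i, v in enumerate(rng.normal(size=50))}
        cs = ClusterSet.from_labels([0] * 50)
        arr = np.array(list(vals.values()))
        assert pooled_variance(vals, cs) == pytest.approx(np.var(arr, ddof=1))

    def test_hand_computed_two_cluster_example(self):
        # sizes 3 and 3 with sample variances 2 and 4 -> (2*2 + 2*4)/4 = 3
        c1 = [-np.sqrt(2), 0.0, np.sqrt(2)]  # s^2 = 2
        c2 = [-2.0, 0.0, 2.0]                # s^2 = 4
        vals = dict(enumerate(c1 + c2))
        cs = ClusterSet.from_labels([0, 0, 0, 1, 1, 1])
        assert pooled_variance(vals, cs) == pytest.approx(3.0)

    def test_identical_values_give_zero(self):
        vals = dict(enumerate([2.0] * 6))
        cs = ClusterSet.from_labels([0, 0, 0, 1, 1, 1])
        assert pooled_variance(vals, cs) == 0.0

    def test_all_singletons_undefined(self):
        vals = {0: 1.0, 1: 2.0}
        cs = ClusterSet.from_labels([0, 1])
        with pytest.raises(UndefinedVarianceError):
            pooled_variance(vals, cs)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        vals = dict(enumerate(rng.normal(size=30)))
        labels = rng.integers(0, 5, size=30)
        a = pooled_variance(vals, ClusterSet.from_labels(labels))
        b = pooled_variance(vals, ClusterSet.from_labels(4 - labels))
        assert a == pytest.approx(b)


class TestHomogeneity:
    def test_random_partition_ratio_near_one(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        props = pd.DataFrame({"p": rng.normal(size=400)})
        cs = ClusterSet.from_labels(rng.integers(0, 20, size=400))
        report = homogeneity_report(props, cs)
        assert report.loc["p", "ratio"] == pytest.approx(1.0, abs=0.25)

    def test_sorted_clusters_ratio_large(self):
        import pandas as pd

        vals = np.sort(np.random.default_rng(7).normal(size=400))
        props = pd.DataFrame({"p": vals})
        cs = ClusterSet.from_labels(np.repeat(np.arange(20), 20))
        report = homogeneity_report(props, cs)
        assert report.loc["p", "ratio"] > 5

    def test_eight_property_rows(self, toy_model):
        import pandas as pd

        from cdr3vec.biophys import property_table

        grams = sorted(toy_model.vocab_)[:40]
        props = property_table(grams)
        props.index = range(len(grams))
        cs = ClusterSet.from_labels(np.arange(len(grams)) // 10)
        report = homogeneity_report(props, cs)
        assert report.shape == (8, 3)


class TestDistanceDistribution:
    def test_sorted_clusters_significant(self):
        vals = dict(enumerate(np.sort(np.random.default_rng(8).normal(size=200))))
        cs = ClusterSet.from_labels(np.repeat(np.arange(10), 20))
        res = distance_distribution_test(vals, cs)
        assert res["p_value"] < 1e-5

    def test_single_cluster_null(self):
        vals = dict(enumerate(np.random.default_rng(9).normal(size=60)))
        cs = ClusterSet.from_labels([0] * 60)
        res = distance_distribution_test(vals, cs)
        # identical distributions: p should be unremarkable
        assert res["p_value"] > 0.3

    def test_minimal_two_member_case(self):
        res = distance_distribution_test({0: 1.0, 1: 2.0}, ClusterSet.from_labels([0, 0]))
        assert np.isfinite(res["p_value"])


class TestMoransI:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(20, 120))
            pts = rng.uniform(0, 10, size=(n, 2))
            vals = rng.normal(size=n)
            d_x = float(rng.uniform(1, 8))
            try:
                res = morans_i(pts, vals, d_x)
            except NoNeighborsError:
                continue
            assert res.I == pytest.approx(brute_force_morans_i(pts, vals, d_x), abs=1e-10)

    def test_two_blob_construction_equals_one(self):
        rng = np.random.default_rng(11)
        blob1 = rng.uniform(0, 1, size=(30, 2))
        blob2 = rng.uniform(100, 101, size=(30, 2))
        pts = np.vstack([blob1, blob2])
        vals = np.array([1.0] * 30 + [-1.0] * 30)
        res = morans_i(pts, vals, d_x=5.0)  # smaller than inter-blob gap
        assert res.I == pytest.approx(1.0)

    def test_constant_values_error(self):
        pts = np.random.default_rng(12).uniform(size=(20, 2))
        with pytest.raises(ZeroVarianceError):
            morans_i(pts, np.ones(20), 1.0)

    def test_no_neighbors_error(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        with pytest.raises(NoNeighborsError):
            morans_i(pts, [1.0, 2.0], d_x=0.5)

    def test_random_signal_near_zero(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 10, size=(200, 2))
        vals = rng.normal(size=200)
        res = morans_i(pts, vals, 3.0)
        assert abs(res.I) < 0.1


class TestMoransProfile:
    def test_smooth_signal_decays_with_distance(self):
        rng = np.random.default_rng(14)
        pts = rng.uniform(0, 10, size=(300, 2))
        vals = pts[:, 0]  # spatially smooth gradient
        profile = morans_profile(pts, vals, [1.0, 3.0, 8.0, 14.0])
        Is = [r.I for r in profile]
        assert Is[0] > 0.5
        assert Is[0] > Is[1] > Is[2] > Is[3]
        assert abs(Is[3]) < 0.1

    def test_empty_distance_list(self):
        pts = np.random.default_rng(15).uniform(size=(10, 2))
        assert morans_profile(pts, pts[:, 0], []) == []

    def test_skips_distances_without_neighbors(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        with pytest.warns(UserWarning):
            profile = morans_profile(pts, [1.0, 2.0, 3.0], [0.5, 15.0])
        assert len(profile) == 1
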