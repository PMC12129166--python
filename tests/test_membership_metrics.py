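import numpy as np
import pytest
from oracles import (
    bf_cms,
    bf_cosine,
    bf_euclidean,
    bf_gaussian,
    bf_knn,
    bf_silhouette,
    random_cluster_instance,
)

from bowelgrade.errors import (
    InvalidArgumentError,
    InvalidInputError,
    UndefinedScoreError,
)
from bowelgrade.membership_metrics import (
    METRIC_NAMES,
    ORIENTATION,
    ControlCluster,
    MetricConfig,
    cluster_membership_strength,
    cosine_to_centroid,
    default_sigma,
    euclidean_to_centroid,
    gaussian_membership,
    grade_segments,
    knn_grade,
    silhouette_singleton,
    zscore_fit_transform,
)


class TestZScore:
    def test_pooled_two_point_column(self):
        cluster, ztests, names = zscore_fit_transform(
            np.array([[0.0], [2.0]]), np.empty((0, 1))
        )
        assert np.allclose(cluster.members.ravel(), [-0.70710678, 0.70710678])

    def test_idempotence(self, rng):
        control = rng.standard_normal((10, 3))
        tests = rng.standard_normal((4, 3))
        c1, t1, _ = zscore_fit_transform(control, tests)
        c2, t2, _ = zscore_fit_transform(c1.members, t1)
        assert np.allclose(c1.members, c2.members, atol=1e-12)
        assert np.allclose(t1, t2, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng, caplog):
        control = np.column_stack([np.full(5, 3.0), rng.standard_normal(5)])
        tests = np.column_stack([np.full(2, 3.0), rng.standard_normal(2)])
        cluster, zt, names = zscore_fit_transform(control, tests, ("a", "b"))
        assert names == ("b",)
        assert cluster.members.shape[1] == 1
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_all_constant_rejected(self):
        with pytest.raises(InvalidInputError):
            zscore_fit_transform(np.ones((4, 2)), np.ones((2, 2)))


class TestEuclidean:
    def test_centroid_itself_and_pythagoras(self, rng):
        members = rng.standard_normal((6, 2))
        c = ControlCluster(members)
        assert euclidean_to_centroid(c.centroid, c) == 0.0
        c2 = ControlCluster(np.array([[1.0, 1.0], [-1.0, -1.0]]))  # centroid (0,0)
        assert euclidean_to_centroid(np.array([3.0, 4.0]), c2) == pytest.approx(5.0)

    def test_translation_invariance(self, rng):
        members = rng.standard_normal((5, 3))
        x = rng.standard_normal(3)
        t = rng.standard_normal(3)
        d1 = euclidean_to_centroid(x, ControlCluster(members))
        d2 = euclidean_to_centroid(x + t, ControlCluster(members + t))
        assert d1 == pytest.approx(d2)

    def test_dimension_mismatch(self, small_cluster):
        with pytest.raises(InvalidArgumentError):
            euclidean_to_centroid(np.array([1.0, 2.0]), small_cluster)


class TestSilhouette:
    def test_hand_worked_fixture(self, small_cluster):
        # controls {0,2}, x=10: member scores 0.8 and 0.75, singleton 0
        s = silhouette_singleton(np.array([10.0]), small_cluster)
        assert s == pytest.approx((0.8 + 0.75 + 0.0) / 3)

    def test_member_coincident_with_x_scores_minus_one(self, small_cluster):
        # x at member 0: that member's b=0 -> s=-1; the other: a=2, b=2 -> 0
        s = silhouette_singleton(np.array([0.0]), small_cluster)
        assert s == pytest.approx((-1.0 + 0.0 + 0.0) / 3)

    def test_monotone_in_distance(self, small_cluster):
        xs = np.linspace(3.0, 50.0, 25)
        scores = [silhouette_singleton(np.array([v]), small_cluster) for v in xs]
        assert np.all(np.diff(scores) >= -1e-12)

    def test_singleton_convention_is_rank_neutral(self, rng):
        """Replacing the singleton's 0 by any constant shifts every mean by
        the same amount and cannot reorder test segments."""
        members = rng.standard_normal((6, 2))
        c = ControlCluster(members)
        tests = rng.standard_normal((8, 2)) * 2
        base = np.array([silhouette_singleton(x, c) for x in tests])
        shifted = base + 1.0 / (c.n + 1)  # singleton scored 1 instead of 0
        assert np.array_equal(np.argsort(base), np.argsort(shifted))


class TestCosine:
    def test_aligned_opposed_orthogonal(self):
        c = ControlCluster(np.array([[2.0, 0.0], [4.0, 0.0]]))  # centroid (3,0)
        assert cosine_to_centroid(np.array([3.0, 0.0]), c) == pytest.approx(1.0)
        assert cosine_to_centroid(np.array([-3.0, 0.0]), c) == pytest.approx(-1.0)
        assert cosine_to_centroid(np.array([0.0, 1.0]), c) == pytest.approx(0.0)

    def test_zero_norm_undefined(self):
        c = ControlCluster(np.array([[1.0], [3.0]]))
        with pytest.raises(UndefinedScoreError):
            cosine_to_centroid(np.array([0.0]), c)


class TestKnnAndCms:
    def test_knn_examples(self):
        c = ControlCluster(np.array([[1.0], [2.0], [3.0]]))
        assert knn_grade(np.array([1.0]), c, 1) == 0.0
        # distances from 0 are {1,2,3}: k=2 -> 1.5
        assert knn_grade(np.array([0.0]), c, 2) == pytest.approx(1.5)
        assert knn_grade(np.array([0.0]), c, 3) == pytest.approx(2.0)

    def test_knn_tie_break_by_member_index(self):
        # members 1 and 3 are both at distance 1 from x=2
        c = ControlCluster(np.array([[1.0], [3.0], [10.0]]))
        assert knn_grade(np.array([2.0]), c, 1) == pytest.approx(1.0)

    def test_knn_k_out_of_range(self, small_cluster):
        with pytest.raises(InvalidArgumentError):
            knn_grade(np.array([0.0]), small_cluster, 3)

    def test_cms_values(self, small_cluster):
        # distances from x=1 to {0,2} are {1,1} -> 1/(1+eps)
        assert cluster_membership_strength(
            np.array([1.0]), small_cluster, eps=1e-12
        ) == pytest.approx(1.0, abs=1e-9)
        # x=3 against {0,2}: distances {3,1}, mean 2 -> cms 0.5
        assert cluster_membership_strength(
            np.array([3.0]), small_cluster, eps=1e-12
        ) == pytest.approx(0.5, abs=1e-9)

    def test_cms_at_coincident_members_hits_guard(self):
        c = ControlCluster(np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]]))
        assert cluster_membership_strength(
            np.array([1.0, 1.0]), c, eps=1e-6
        ) == pytest.approx(1e6)

    def test_cms_knn_identity_at_full_k(self, rng):
        for _ in range(20):
            x, members = random_cluster_instance(rng)
            c = ControlCluster(members)
            eps = 1e-12
            assert cluster_membership_strength(x, c, eps) == pytest.approx(
                1.0 / (knn_grade(x, c, c.n) + eps), rel=1e-12
            )


class TestGaussian:
    def test_centroid_and_sigma_point(self, rng):
        members = rng.standard_normal((5, 2))
        c = ControlCluster(members)
        assert gaussian_membership(c.centroid, c) == pytest.approx(1.0)
        sigma = 1.7
        d = euclidean_to_centroid(c.centroid + np.array([sigma, 0.0]), c)
        m = gaussian_membership(c.centroid + np.array([sigma, 0.0]), c, sigma=d)
        assert m == pytest.approx(np.exp(-0.5))

    def test_ranking_reverse_of_distance_for_any_sigma(self, rng):
        members = rng.standard_normal((8, 3))
        c = ControlCluster(members)
        tests = rng.standard_normal((10, 3)) * 2
        d = np.array([euclidean_to_centroid(x, c) for x in tests])
        # sigma small enough to underflow exp(-d^2/2s^2) to 0 would create
        # artificial ties; any sigma within float range preserves the duality
        for sigma in (0.5, 1.0, 5.0):
            m = np.array([gaussian_membership(x, c, sigma) for x in tests])
            assert np.array_equal(np.argsort(d), np.argsort(-m))


class TestGradeSegments:
    def test_brute_force_oracle_on_seeded_fixture(self, rng):
        members = rng.standard_normal((5, 2))
        tests = rng.standard_normal((3, 2)) * 1.5
        c = ControlCluster(members)
        cfg = MetricConfig(k=3, eps=1e-12, sigma=1.3)
        scores = grade_segments(tests, c, cfg)
        for i, x in enumerate(tests):
            assert scores.raw.iloc[i]["euclidean"] == pytest.approx(
                bf_euclidean(x, members), rel=1e-9
            )
            assert scores.raw.iloc[i]["silhouette"] == pytest.approx(
                bf_silhouette(x, members), rel=1e-9
            )
            assert scores.raw.iloc[i]["cosine"] == pytest.approx(
                bf_cosine(x, members), rel=1e-9
            )
            assert scores.raw.iloc[i]["knn"] == pytest.approx(
                bf_knn(x, members, 3), rel=1e-9
            )
            assert scores.raw.iloc[i]["cms"] == pytest.approx(
                bf_cms(x, members, 1e-12), rel=1e-9
            )
            assert scores.raw.iloc[i]["gaussian"] == pytest.approx(
                bf_gaussian(x, members, 1.3), rel=1e-9
            )

    def test_orientation_signs_applied(self, rng):
        members = rng.standard_normal((5, 2))
        tests = rng.standard_normal((3, 2))
        scores = grade_segments(tests, ControlCluster(members))
        for m in METRIC_NAMES:
            assert np.allclose(
                scores.activity[m], ORIENTATION[m] * scores.raw[m], equal_nan=True
            )

    def test_centroid_vector_minimizes_distance_scores(self, rng):
        members = rng.standard_normal((6, 3))
        c = ControlCluster(members)
        tests = np.vstack([c.centroid, rng.standard_normal((4, 3)) + 2.0])
        scores = grade_segments(tests, c)
        for m in ("euclidean", "gaussian"):
            assert scores.activity[m].idxmin() == 0

    def test_identical_tests_identical_records(self, rng):
        members = rng.standard_normal((5, 2))
        x = rng.standard_normal(2)
        scores = grade_segments(np.vstack([x, x]), ControlCluster(members))
        assert scores.raw.iloc[0].equals(scores.raw.iloc[1])

    def test_member_permutation_invariance(self, rng):
        members = rng.standard_normal((7, 2))
        tests = rng.standard_normal((4, 2))
        perm = rng.permutation(7)
        s1 = grade_segments(tests, ControlCluster(members), MetricConfig(k=3))
        s2 = grade_segments(tests, ControlCluster(members[perm]), MetricConfig(k=3))
        for m in METRIC_NAMES:
            assert np.allclose(s1.raw[m], s2.raw[m], rtol=1e-12)
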