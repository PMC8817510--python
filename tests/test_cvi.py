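import numpy as np
import pytest

from icpshape.cvi import (
    calinski_harabasz,
    cvi_compare,
    cvi_report,
    davies_bouldin,
    silhouette,
)
from icpshape.synthetic import generate_shape_set


def brute_force_silhouette(X, labels):
    """Independent pairwise-enumeration silhouette (Euclidean)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(labels):
        X = X.T
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            s[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == u])
            for u in set(labels) if u != labels[i]
        )
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


class TestSilhouette:
    def test_duplicates_far_apart_score_one(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        per, mean = silhouette(X, [0, 0, 1, 1], distance="euclidean")
        assert np.allclose(per, 1.0)
        assert mean == 1.0

    def test_equidistant_point_scores_zero(self):
        X = np.array([[0.0], [0.0], [5.0], [10.0], [10.0]])
        per, _ = silhouette(X, [0, 0, 0, 1, 1], distance="euclidean")
        # the point at 5: a = mean(5,5) = 5, b = mean(5,5) = 5
        assert per[2] == pytest.approx(0.0, abs=1e-12)

    def test_scalar_case_matches_enumeration(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = [0, 0, 0, 1, 1, 1]
        per, mean = silhouette(X, labels, distance="euclidean")
        oracle = brute_force_silhouette(X, labels)
        assert np.max(np.abs(per - oracle)) < 1e-10
        assert mean == pytest.approx(oracle.mean(), abs=1e-10)

    def test_random_labelings_match_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 21))
            k = int(rng.integers(2, min(n, 5)))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, n)
            if np.unique(labels).size < 2:
                continue
            per, _ = silhouette(X, labels, distance="euclidean")
            assert np.max(np.abs(per - brute_force_silhouette(X, labels))) < 1e-10

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import silhouette_score

        X = rng.normal(size=(40, 4))
        labels = rng.integers(0, 3, 40)
        _, mean = silhouette(X, labels, distance="euclidean")
        assert mean == pytest.approx(silhouette_score(X, labels), abs=1e-10)

    def test_values_in_range_and_permutation_invariant(self, rng):
        X = rng.normal(size=(25, 2))
        labels = rng.integers(0, 4, 25)
        per, mean = silhouette(X, labels, distance="euclidean")
        assert np.all(per >= -1) and np.all(per <= 1)
        remap = {0: 3, 1: 0, 2: 2, 3: 1}
        per2, mean2 = silhouette(X, [remap[v] for v in labels], distance="euclidean")
        assert mean2 == pytest.approx(mean, abs=1e-12)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), [0] * 5)

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [9.0]])
        per, _ = silhouette(X, [0, 0, 1], distance="euclidean")
        assert per[2] == 0.0


class TestDaviesBouldin:
    def test_zero_scatter_toy(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        dbi, omd = davies_bouldin(X, [0, 0, 1, 1], np.array([[0.0], [10.0]]),
                                  distance="euclidean")
        assert dbi == 0.0 and omd == 1.0

    def test_hand_computed_toy(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        dbi, omd = davies_bouldin(X, [0, 0, 1, 1], np.array([[1.0], [11.0]]),
                                  distance="euclidean")
        assert dbi == pytest.approx(0.2, abs=1e-12)
        assert omd == pytest.approx(0.8, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import davies_bouldin_score

        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, 30)
        cents = np.vstack([X[labels == u].mean(axis=0) for u in np.unique(labels)])
        dbi, _ = davies_bouldin(X, labels, cents, distance="euclidean")
        assert dbi == pytest.approx(davies_bouldin_score(X, labels), abs=1e-10)

    def test_permutation_invariant(self, rng):
        X = rng.normal(size=(20, 2))
        labels = rng.integers(0, 3, 20)
        cents = np.vstack([X[labels == u].mean(axis=0) for u in np.unique(labels)])
        dbi1, _ = davies_bouldin(X, labels, cents, distance="euclidean")
        remap = {0: 2, 1: 0, 2: 1}
        labels2 = np.array([remap[v] for v in labels])
        cents2 = np.vstack([X[labels2 == u].mean(axis=0) for u in np.unique(labels2)])
        dbi2, _ = davies_bouldin(X, labels2, cents2, distance="euclidean")
        assert dbi1 == pytest.approx(dbi2, abs=1e-12)

    def test_coincident_centroids_rejected(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(X, [0, 0, 1, 1], np.array([[1.0], [1.0]]),
                           distance="euclidean")


class TestCalinskiHarabasz:
    def test_zero_within_scatter_is_inf(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert calinski_harabasz(X, [0, 0, 1, 1]) == np.inf

    def test_hand_computed_toy(self):
        # between-SS = 100, within-SS = 4, (n-K)/(K-1) = 2
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert calinski_harabasz(X, [0, 0, 1, 1]) == pytest.approx(50.0, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        X = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, 30)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-10
        )

    def test_legacy_correction_factor(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        # (100/4) * (n_p - 1)/(n_p - K) = 25 * 3/2
        assert calinski_harabasz(X, [0, 0, 1, 1], legacy_correction=True) == \
            pytest.approx(37.5, abs=1e-12)

    def test_noise_dimensions_decrease_chi(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 1)), rng.normal(8, 0.2, (15, 1))])
        labels = [0] * 15 + [1] * 15
        base = calinski_harabasz(X, labels)
        noisy = calinski_harabasz(np.hstack([X, rng.normal(size=(30, 5))]), labels)
        assert noisy < base


class TestCompare:
    def test_identical_labelings_zero_delta(self, rng):
        Z, labels = generate_shape_set(["sinusoid", "peak"], 10, m=64, seed=0)
        from icpshape.kshape import kshape_cluster

        model = kshape_cluster(Z, 2, seed=0)
        out = cvi_compare(Z, model.labels, model.labels, model.centroids)
        assert out["delta"]["silhouette"] == pytest.approx(0.0, abs=1e-12)
        assert out["delta"]["chi"] == pytest.approx(0.0, abs=1e-9)

    def test_gating_noise_improves_silhouette(self, rng):
        # two clean clusters plus white-noise contaminants assigned to
        # cluster 1; the correlation gate drops the contaminants
        from icpshape.kshape import sbd as sbd_fn

        Z, labels = generate_shape_set(["sinusoid", "descend"], 15, m=64,
                                       noise_sd=0.02, seed=3)
        noise = rng.normal(size=(8, 64))
        noise = (noise - noise.mean(axis=1, keepdims=True)) / noise.std(axis=1, keepdims=True)
        Zall = np.vstack([Z, noise])
        lab_all = np.concatenate([labels + 1, np.ones(8, int)])
        cents = np.vstack([Zall[lab_all == u].mean(axis=0) for u in (1, 2)])
        cents = (cents - cents.mean(axis=1, keepdims=True)) / cents.std(axis=1, keepdims=True)
        # correlation rule: keep only subsequences with cc > 0.5 to their centroid
        lab_gated = lab_all.copy()
        for i in range(Zall.shape[0]):
            if 1 - sbd_fn(Zall[i], cents[lab_all[i] - 1])[0] <= 0.5:
                lab_gated[i] = 0
        assert (lab_gated == 0).sum() >= 4  # gate actually fires on noise
        out = cvi_compare(Zall, lab_all, lab_gated, cents)
        assert out["delta"]["silhouette"] > 0

    def test_empty_retained_rejected(self):
        Z = np.random.default_rng(0).normal(size=(6, 8))
        with pytest.raises(ValueError):
            cvi_compare(Z, [1, 1, 1, 2, 2, 2], [0, 0, 0, 0, 0, 0],
                        np.zeros((2, 8)))


def test_report_fields(rng):
    Z, labels = generate_shape_set(["sinusoid", "ascend"], 8, m=32, seed=1)
    from icpshape.kshape import kshape_cluster

    model = kshape_cluster(Z, 2, seed=0)
    rep = cvi_report(Z, model.labels, model.centroids, distance="sbd")
    assert -1 <= rep.silhouette_mean <= 1
    assert rep.one_minus_dbi == pytest.approx(1 - rep.dbi)
    assert rep.chi >= 0
    assert rep.n_p == 16 and rep.K == 2
    assert rep.distance_name == "sbd"
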