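"""Two-level clustering: active prototypes, K-means, Davies-Bouldin,
K-scan/selection and propagation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from swaysom import cluster, som
from swaysom.errors import (
    DegenerateClusteringError,
    EmptyResultError,
    InvalidArgumentError,
)


def db_oracle(points, labels):
    """Direct-from-formula Davies-Bouldin with sigma = RMS distance."""
    clusters = sorted(set(labels))
    mus, sigmas = [], []
    for c in clusters:
        members = points[labels == c]
        mu = members.mean(axis=0)
        mus.append(mu)
        sigmas.append(np.sqrt(np.mean([np.sum((m - mu) ** 2) for m in members])))
    db_i = []
    for i in range(len(clusters)):
        vals = []
        for j in range(len(clusters)):
            if i == j:
                continue
            gap = np.linalg.norm(np.array(mus[i]) - np.array(mus[j]))
            vals.append((sigmas[i] + sigmas[j]) / gap)
        db_i.append(max(vals))
    return float(np.mean(db_i))


def wcss_of(points, labels, centroids):
    return float(
        sum(np.sum((points[labels == k] - centroids[k]) ** 2)
            for k in range(len(centroids)))
    )


class TestActivePrototypes:
    def test_all_hits_on_one_neuron_gives_data_mean(self, rng, small_grid):
        w = np.full((16, 2), 100.0)
        w[5] = [0.0, 0.0]
        model = som.SOMModel(small_grid, w)
        data = rng.normal(0, 1, (12, 2))
        protos = cluster.active_prototypes(model, data)
        assert protos.n_prototypes == 1
        assert np.allclose(protos.vectors[0], data.mean(axis=0))

    def test_member_counts_partition_the_data(self, rng):
        g = som.SOMGrid(10, 10)
        data = rng.normal(0, 1, (46, 2))
        model = som.train_batch(data, g, iterations=100, seed=0)
        protos = cluster.active_prototypes(model, data)
        sizes = [len(m) for m in protos.member_ids]
        assert sum(sizes) == 46
        assert min(sizes) >= 1
        all_ids = np.sort(np.concatenate(protos.member_ids))
        assert np.array_equal(all_ids, np.arange(46))

    def test_singleton_prototype_equals_its_sample(self, rng, small_grid):
        model = som.SOMModel(small_grid, np.eye(16, 2) * 100)
        data = np.array([[100.0, 0.0]])
        protos = cluster.active_prototypes(model, data)
        assert np.allclose(protos.vectors[0], data[0])

    def test_empty_data_rejected(self, small_grid):
        model = som.SOMModel(small_grid, np.zeros((16, 2)))
        with pytest.raises(EmptyResultError):
            cluster.active_prototypes(model, np.empty((0, 2)))


class TestKmeans:
    def test_k_equals_n_gives_zero_wcss(self, rng):
        pts = rng.normal(0, 1, (6, 2))
        res = cluster.kmeans(pts, K=6, seed=0, n_init=5)
        assert res.wcss == pytest.approx(0.0, abs=1e-20)
        assert len(set(res.labels)) == 6

    def test_k_one_gives_global_mean(self, rng):
        pts = rng.normal(0, 1, (10, 3))
        res = cluster.kmeans(pts, K=1, seed=0)
        assert np.allclose(res.centroids[0], pts.mean(axis=0))

    def test_two_blob_partition_is_exhaustive_optimum(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        res = cluster.kmeans(pts, K=2, seed=0, n_init=5)
        # exhaustive scan over all 2-partitions
        best = None
        for mask in itertools.product([0, 1], repeat=4):
            if len(set(mask)) < 2:
                continue
            labels = np.array(mask)
            cents = np.array([pts[labels == k].mean(axis=0) for k in (0, 1)])
            w = wcss_of(pts, labels, cents)
            best = w if best is None else min(best, w)
        assert res.wcss == pytest.approx(best)
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]

    def test_wcss_history_monotone_non_increasing(self, rng):
        pts = rng.normal(0, 1, (60, 3))
        res = cluster.kmeans(pts, K=5, seed=2)
        assert all(b <= a + 1e-9 for a, b in zip(res.history, res.history[1:]))

    def test_final_assignment_is_a_local_optimum(self, rng):
        pts = rng.normal(0, 1, (30, 2))
        res = cluster.kmeans(pts, K=4, seed=1, n_init=5)
        # no single point is closer to another centroid than to its own
        d2 = np.sum((pts[:, None, :] - res.centroids[None]) ** 2, axis=2)
        assert np.all(
            d2[np.arange(len(pts)), res.labels] <= d2.min(axis=1) + 1e-12
        )

    def test_k_larger_than_points_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            cluster.kmeans(rng.normal(0, 1, (3, 2)), K=4)

    def test_matches_sklearn_on_separable_instance(self, rng):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        pts = np.vstack(
            [rng.normal(0, 0.2, (8, 2)), rng.normal(5, 0.2, (8, 2))]
        )
        ours = cluster.kmeans(pts, K=2, seed=0, n_init=10)
        ref = sklearn_cluster.KMeans(n_clusters=2, n_init=10, random_state=0).fit(pts)
        assert ours.wcss == pytest.approx(ref.inertia_, rel=1e-9)


class TestDaviesBouldin:
    def test_hand_computed_value(self):
        pts = np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]])
        labels = np.array([0, 0, 1, 1])
        assert cluster.davies_bouldin(pts, labels) == pytest.approx(0.2)

    def test_two_singletons_give_zero(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0]])
        assert cluster.davies_bouldin(pts, np.array([0, 1])) == 0.0

    def test_scale_invariance(self, rng):
        pts = rng.normal(0, 1, (20, 2))
        labels = rng.integers(0, 3, 20)
        if len(set(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        a = cluster.davies_bouldin(pts, labels)
        b = cluster.davies_bouldin(pts * 37.5, labels)
        assert a == pytest.approx(b, rel=1e-12)

    def test_coincident_centroids_rejected(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        with pytest.raises(DegenerateClusteringError):
            cluster.davies_bouldin(pts, np.array([0, 0, 1, 1]))

    def test_matches_direct_formula_oracle(self, rng):
        for trial in range(25):
            n = int(rng.integers(6, 21))
            k = int(rng.integers(2, min(n, 5)))
            pts = rng.normal(0, 1, (n, 2))
            labels = rng.integers(0, k, n)
            if len(set(labels.tolist())) < 2:
                continue
            assert cluster.davies_bouldin(pts, labels) == pytest.approx(
                db_oracle(pts, labels), abs=1e-12
            )


class TestScanAndSelectK:
    def test_two_blob_fixture_minimum_at_k2(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.3, (10, 2)), rng.normal(8, 0.3, (10, 2))]
        )
        curve, minima = cluster.scan_k(pts, k_range=range(2, 8), reps=3, seed=0)
        best = int(curve.loc[curve["mean_db"].idxmin(), "K"])
        assert best == 2
        assert 2 in minima

    def test_curve_deterministic_given_seed(self, rng):
        pts = rng.normal(0, 1, (15, 2))
        c1, _ = cluster.scan_k(pts, k_range=range(2, 6), reps=2, seed=9)
        c2, _ = cluster.scan_k(pts, k_range=range(2, 6), reps=2, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_oversized_range_clipped_with_warning(self, rng, caplog):
        pts = rng.normal(0, 1, (8, 2))
        with caplog.at_level("WARNING", logger="swaysom.cluster"):
            curve, _ = cluster.scan_k(pts, k_range=range(2, 31), reps=1, seed=0)
        assert curve["K"].max() == 7
        assert any("clipped" in rec.message for rec in caplog.records)

    def test_select_k_highest_f_among_minima(self):
        curve = pd.DataFrame({"K": [2, 4, 9], "mean_db": [0.5, 0.6, 0.7]})
        f = {2: 0.717, 4: 0.448, 9: 0.249}
        assert cluster.select_k(curve, [2, 4, 9], f) == 2

    def test_select_k_single_candidate(self):
        curve = pd.DataFrame({"K": [3], "mean_db": [0.4]})
        assert cluster.select_k(curve, [3], {3: 0.5}) == 3

    def test_select_k_tie_goes_to_smaller_k(self):
        curve = pd.DataFrame({"K": [2, 4], "mean_db": [0.5, 0.4]})
        assert cluster.select_k(curve, [2, 4], {2: 0.6, 4: 0.6}) == 2

    def test_select_k_no_candidates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cluster.select_k(pd.DataFrame({"K": [], "mean_db": []}), [], {})


class TestPropagate:
    def _protos(self, member_lists):
        vectors = np.zeros((len(member_lists), 2))
        return cluster.PrototypeSet(
            vectors=vectors,
            member_ids=[np.array(m) for m in member_lists],
            neuron_indices=np.arange(len(member_lists)),
        )

    def test_singleton_prototypes_identity_mapping(self):
        protos = self._protos([[0], [1], [2]])
        labels = np.array([2, 0, 1])
        assert np.array_equal(cluster.propagate(labels, protos), [2, 0, 1])

    def test_counts_conserved(self):
        protos = self._protos([[0, 3], [1, 2, 4]])
        out = cluster.propagate(np.array([1, 0]), protos)
        assert np.sum(out == 1) == 2 and np.sum(out == 0) == 3

    def test_matches_manual_join_on_ten_points(self, rng):
        members = [[0, 5], [1, 6, 7], [2], [3, 8, 9], [4]]
        protos = self._protos(members)
        labels = np.array([0, 1, 1, 0, 2])
        out = cluster.propagate(labels, protos)
        manual = np.empty(10, dtype=int)
        for p, mlist in enumerate(members):
            for m in mlist:
                manual[m] = labels[p]
        assert np.array_equal(out, manual)

    def test_label_count_mismatch_rejected(self):
        protos = self._protos([[0], [1]])
        with pytest.raises(InvalidArgumentError):
            cluster.propagate(np.array([0]), protos)
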