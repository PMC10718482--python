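"""TADPole density peaks, pruning equivalence, medoids, silhouette, selection."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from _oracles import density_peaks_full, silhouette_brute
from actipat.dtw import pairwise_dtw
from actipat.tsclust import (
    DtwOracle,
    density_and_separation,
    medoid,
    select_model,
    silhouette_index,
    tadpole,
)


def canonical(labels) -> list[int]:
    """Relabel a partition into first-appearance order for comparison."""
    seen: dict = {}
    return [seen.setdefault(v, len(seen)) for v in labels]


def two_bundles(rng, n_per=3, length=20, gap=50.0):
    a = rng.normal(size=length).cumsum()
    b = a + gap
    X = np.vstack(
        [a + rng.normal(0, 0.05, length) for _ in range(n_per)]
        + [b + rng.normal(0, 0.05, length) for _ in range(n_per)]
    )
    return X


class TestDensityAndSeparation:
    def test_three_point_example(self):
        D = np.array([[0.0, 1, 5], [1, 0, 5], [5, 5, 0]])
        rho, delta, nhd, _ = density_and_separation(D, cutoff=2.0)
        assert rho.tolist() == [1, 1, 0]
        # index tie-break: series 0 counts as denser than series 1
        assert delta.tolist() == [5.0, 1.0, 5.0]
        assert nhd.tolist() == [-1, 0, 0]

    def test_cutoff_above_max_gives_full_density(self, rng):
        X = rng.normal(size=(6, 15))
        D = pairwise_dtw(X, 2)
        rho, _, _, _ = density_and_separation(D, cutoff=D.max() + 1)
        assert (rho == 5).all()

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            density_and_separation(np.zeros((3, 3)), cutoff=0.0)

    def test_pruned_equals_full_matrix(self, rng):
        """Bound-based pruning must not change rho, delta or the neighbour."""
        for _ in range(25):
            n = int(rng.integers(5, 26))
            length = int(rng.integers(6, 20))
            w = int(rng.integers(0, 5))
            X = rng.normal(size=(n, length)).cumsum(axis=1)
            D = pairwise_dtw(X, w)
            cutoff = float(np.quantile(D[np.triu_indices(n, 1)], rng.uniform(0.1, 0.7)))
            if cutoff <= 0:
                continue
            r1, d1, n1, _ = density_and_separation(DtwOracle(X, w), cutoff)
            r2, d2, n2, _ = density_and_separation(D, cutoff)
            assert np.array_equal(r1, r2)
            assert np.allclose(d1, d2)
            assert np.array_equal(n1, n2)

    def test_pruning_skips_exact_computations(self, rng):
        X = rng.normal(size=(20, 40)).cumsum(axis=1)
        D = pairwise_dtw(X, 3)
        cutoff = float(np.quantile(D[np.triu_indices(20, 1)], 0.3))
        oracle = DtwOracle(X, 3)
        _, _, _, dmat = density_and_separation(oracle, cutoff)
        assert dmat.n_pruned > 0
        assert oracle.n_exact_pairs() < 190


class TestTadpole:
    def test_k1_single_cluster(self, rng):
        X = rng.normal(size=(5, 12))
        model = tadpole(X, k=1, cutoff=1.0, window=2)
        assert set(model.assignment) == {0}

    def test_recovers_two_bundles(self, rng):
        X = two_bundles(rng)
        D = pairwise_dtw(X, 2)
        cutoff = float(np.quantile(D[np.triu_indices(6, 1)], 0.4))
        model = tadpole(X, k=2, cutoff=cutoff, window=2)
        assert canonical(model.assignment) == [0, 0, 0, 1, 1, 1]

    def test_matches_full_matrix_density_peaks_oracle(self, rng):
        """Pruned TADPole equals an independent density-peaks pass, n <= 25."""
        for _ in range(20):
            n = int(rng.integers(6, 26))
            X = rng.normal(size=(n, int(rng.integers(8, 16)))).cumsum(axis=1)
            w = int(rng.integers(0, 4))
            D = pairwise_dtw(X, w)
            cutoff = float(np.quantile(D[np.triu_indices(n, 1)], 0.4))
            if cutoff <= 0:
                continue
            k = int(rng.integers(2, 5))
            model = tadpole(X, k=k, cutoff=cutoff, window=w, score=False)
            rho_o, delta_o, labels_o = density_peaks_full(D, k, cutoff)
            assert np.array_equal(model.rho, rho_o)
            assert np.allclose(model.delta, delta_o)
            assert canonical(model.assignment) == canonical(labels_o)

    def test_duplicated_series_share_a_cluster(self, rng):
        X = two_bundles(rng)
        X = np.vstack([X, X[0]])  # exact duplicate of series 0
        D = pairwise_dtw(X, 2)
        cutoff = float(np.quantile(D[np.triu_indices(len(X), 1)], 0.4))
        model = tadpole(X, k=2, cutoff=cutoff, window=2)
        assert model.assignment[6] == model.assignment[0]

    def test_partition_invariant_to_input_order(self, rng):
        X = two_bundles(rng, n_per=4)
        perm = rng.permutation(len(X))
        D = pairwise_dtw(X, 2)
        cutoff = float(np.quantile(D[np.triu_indices(len(X), 1)], 0.4))
        m1 = tadpole(X, k=2, cutoff=cutoff, window=2, score=False)
        m2 = tadpole(X[perm], k=2, cutoff=cutoff, window=2, score=False)
        # same partition up to label names: compare co-membership
        inv = np.argsort(perm)
        a1 = np.asarray(canonical(m1.assignment))
        a2 = np.asarray(canonical(m2.assignment[inv]))
        assert np.array_equal(
            a1[:, None] == a1[None, :], a2[:, None] == a2[None, :]
        )

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            tadpole(rng.normal(size=(3, 10)), k=4, cutoff=1.0, window=1)


class TestMedoid:
    def test_singleton_is_its_own_medoid(self):
        D = np.zeros((4, 4))
        assert medoid(np.array([2]), D) == 2

    def test_three_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 5.0])
        D = np.abs(pts[:, None] - pts[None, :])
        assert medoid(np.array([0, 1, 2]), D) == 1

    def test_invariant_under_member_reordering(self, rng):
        X = rng.normal(size=(6, 10))
        D = pairwise_dtw(X, 2)
        members = np.array([0, 2, 3, 5])
        assert medoid(members, D) == medoid(members[::-1], D)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            medoid(np.array([], dtype=int), np.zeros((3, 3)))


class TestSilhouette:
    def test_hand_example(self):
        # two 2-member clusters: within distance 1, between distance 10
        D = np.array(
            [
                [0.0, 1, 10, 10],
                [1, 0, 10, 10],
                [10, 10, 0, 1],
                [10, 10, 1, 0],
            ]
        )
        assert silhouette_index(D, np.array([0, 0, 1, 1])) == pytest.approx(0.9)

    def test_identical_within_clusters_scores_one(self):
        D = np.array(
            [
                [0.0, 0, 7, 7],
                [0, 0, 7, 7],
                [7, 7, 0, 0],
                [7, 7, 0, 0],
            ]
        )
        assert silhouette_index(D, np.array([0, 0, 1, 1])) == 1.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_index(np.zeros((3, 3)), np.array([0, 0, 0]))

    def test_agrees_with_brute_force_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            X = rng.normal(size=(n, 8))
            D = pairwise_dtw(X, 2)
            labels = rng.integers(0, 3, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            ours = silhouette_index(D, labels)
            assert ours == pytest.approx(silhouette_brute(D, labels), abs=1e-12)
            if min(np.bincount(labels, minlength=3)[np.unique(labels)]) >= 2:
                skl = silhouette_score(D, labels, metric="precomputed")
                assert ours == pytest.approx(skl, abs=1e-9)

    def test_true_partition_beats_random_relabelings(self, rng):
        X = two_bundles(rng, n_per=5)
        D = pairwise_dtw(X, 2)
        truth = np.array([0] * 5 + [1] * 5)
        s_true = silhouette_index(D, truth)
        for _ in range(100):
            shuffled = rng.permutation(truth)
            assert s_true >= silhouette_index(D, shuffled)


class TestSelectModel:
    def test_single_grid_cell_returned(self, rng):
        X = two_bundles(rng)
        D = pairwise_dtw(X, 2)
        cutoff = float(np.quantile(D[np.triu_indices(6, 1)], 0.4))
        model = select_model(X, k_grid=[2], cutoff_grid=[cutoff], window=2)
        assert model.k == 2 and model.cutoff == cutoff

    def test_selected_silhouette_is_grid_maximum(self, rng):
        X = two_bundles(rng, n_per=4)
        model = select_model(X, k_grid=[2, 3, 4], window=2)
        assert model.silhouette == pytest.approx(model.grid["silhouette"].max())

    def test_k1_in_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="k >= 2"):
            select_model(rng.normal(size=(6, 10)), k_grid=[1, 2], window=2)
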