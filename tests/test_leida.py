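"""Phase-coherence matrices, leading eigenvectors, and state clustering."""

import numpy as np
import pytest

import dynfc
from dynfc.leida import relabel_by_order
from dynfc.phase import DataError, PhaseArray


def test_coherence_matrix_stated_example():
    m = dynfc.phase_coherence_matrix(np.array([0.0, np.pi / 3, np.pi]))
    assert m[0, 1] == pytest.approx(0.5)
    assert m[0, 2] == pytest.approx(-1.0)
    assert m[1, 2] == pytest.approx(-0.5)
    assert np.allclose(np.diag(m), 1.0)


def test_coherence_matrix_all_equal_phases_is_all_ones():
    m = dynfc.phase_coherence_matrix(np.full(5, 1.234))
    assert np.allclose(m, 1.0)


def test_coherence_matrix_symmetry_and_range(rng):
    for _ in range(10):
        m = dynfc.phase_coherence_matrix(rng.uniform(-np.pi, np.pi, 12))
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.all((m >= -1 - 1e-12) & (m <= 1 + 1e-12))
        # average eigenvalue is 1 (unit trace/P), so the top one is >= 1
        assert np.linalg.eigvalsh(m)[-1] >= 1 - 1e-9


def test_leading_eigenvector_all_ones_matrix():
    res = dynfc.leading_eigenvector(np.ones((4, 4)))
    assert res.eigenvalue == pytest.approx(4.0)
    assert np.allclose(res.vector, -0.5)


def test_leading_eigenvector_2x2_closed_form():
    res = dynfc.leading_eigenvector(np.array([[1.0, 0.5], [0.5, 1.0]]))
    assert res.eigenvalue == pytest.approx(1.5)
    assert np.allclose(res.vector, -np.sqrt(2) / 2)


def test_leading_eigenvector_requires_symmetry():
    with pytest.raises(DataError, match="symmetric"):
        dynfc.leading_eigenvector(np.array([[1.0, 0.2], [0.5, 1.0]]))


def test_rank2_leida_vectors_match_dense_eigendecomposition(rng):
    """The closed-form rank-2 extraction agrees with a full dense
    eigendecomposition of every per-volume coherence matrix."""
    phases = PhaseArray(rng.uniform(-np.pi, np.pi, size=(100, 12)), trim=0, tr=0.392)
    fast = dynfc.leida_vectors(phases)
    for t in range(phases.n_volumes):
        m = dynfc.phase_coherence_matrix(phases.phases[t])
        dense = dynfc.leading_eigenvector(m)
        assert np.allclose(fast[t], dense.vector, atol=1e-8)
        assert np.allclose(m @ fast[t], dense.eigenvalue * fast[t], atol=1e-8)


def test_fully_synchronised_volume_gives_uniform_eigenvector():
    phases = PhaseArray(np.full((1, 8), 0.7), trim=0, tr=1.0)
    v = dynfc.leida_vectors(phases)[0]
    assert np.allclose(np.abs(v), 1 / np.sqrt(8))
    assert np.all(v <= 0)  # sign convention: majority non-positive


def test_sign_convention_majority_non_positive(rng):
    phases = PhaseArray(rng.uniform(-np.pi, np.pi, size=(200, 11)), trim=0, tr=1.0)
    vectors = dynfc.leida_vectors(phases)
    n_pos = (vectors > 0).sum(axis=1)
    n_neg = (vectors < 0).sum(axis=1)
    assert np.all(n_neg >= n_pos)


class TestClustering:
    def _planted(self, rng, n_per=150, P=10, noise=0.02):
        c1 = np.zeros(P); c1[: P // 2] = 1.0
        c2 = np.zeros(P); c2[P // 2:] = 1.0
        base = np.vstack([np.tile(c1, (n_per, 1)), np.tile(c2, (n_per, 1))])
        vectors = base + noise * rng.standard_normal(base.shape)
        vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
        labels = np.repeat([0, 1], n_per)
        return vectors, labels

    def test_recovers_well_separated_planted_directions(self, rng):
        from sklearn.metrics import adjusted_rand_score

        vectors, truth = self._planted(rng)
        _, labels = dynfc.cluster_eigenvectors(vectors, K=2, seed=0, restarts=5)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k1_centroid_is_the_mean(self, rng):
        vectors, _ = self._planted(rng)
        model, _ = dynfc.cluster_eigenvectors(vectors, K=1, seed=0, restarts=1)
        assert np.allclose(model.centroids[0], vectors.mean(axis=0), atol=1e-9)
        assert model.inertia == pytest.approx(
            ((vectors - vectors.mean(axis=0)) ** 2).sum(), rel=1e-9
        )

    def test_duplicating_inputs_leaves_centroids_unchanged(self, rng):
        vectors, _ = self._planted(rng)
        m1, _ = dynfc.cluster_eigenvectors(vectors, K=2, seed=0, restarts=5)
        m2, _ = dynfc.cluster_eigenvectors(np.vstack([vectors, vectors]), K=2, seed=0, restarts=5)
        c1 = m1.centroids[np.lexsort(m1.centroids.T)]
        c2 = m2.centroids[np.lexsort(m2.centroids.T)]
        assert np.allclose(c1, c2, atol=1e-7)

    def test_seed_determinism_and_restart_monotonicity(self, rng):
        vectors = rng.standard_normal((300, 8))
        m1, l1 = dynfc.cluster_eigenvectors(vectors, K=4, seed=3, restarts=5)
        m2, l2 = dynfc.cluster_eigenvectors(vectors, K=4, seed=3, restarts=5)
        assert np.array_equal(l1, l2) and np.allclose(m1.centroids, m2.centroids)
        few, _ = dynfc.cluster_eigenvectors(vectors, K=4, seed=3, restarts=1)
        many, _ = dynfc.cluster_eigenvectors(vectors, K=4, seed=3, restarts=20)
        assert many.inertia <= few.inertia + 1e-9

    def test_k_larger_than_distinct_vectors_rejected(self):
        vectors = np.tile(np.array([[1.0, 0.0], [0.0, 1.0]]), (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            dynfc.cluster_eigenvectors(vectors, K=3, seed=0)


class TestSelectK:
    def test_planted_three_clusters_optimal_at_k3(self, rng):
        centers = np.eye(3)
        vectors = np.vstack(
            [c + 0.03 * rng.standard_normal((80, 3)) for c in centers]
        )
        table = dynfc.select_k(vectors, k_range=range(2, 7), seed=0, restarts=5)
        best_ch = table.loc[table["calinski_harabasz"].idxmax(), "K"]
        best_db = table.loc[table["davies_bouldin"].idxmin(), "K"]
        assert best_ch == 3 and best_db == 3

    def test_indices_match_textbook_formulas(self, rng):
        """CH and DB computed by sklearn agree with direct implementations
        of the defining formulas on a 30-point toy set."""
        vectors = rng.standard_normal((30, 4))
        _, labels = dynfc.cluster_eigenvectors(vectors, K=3, seed=1, restarts=3)
        table = dynfc.select_k(vectors, k_range=[3], seed=1, restarts=3)

        # direct formulas
        K, n = 3, len(vectors)
        mean = vectors.mean(axis=0)
        cents = np.array([vectors[labels == k].mean(axis=0) for k in range(K)])
        sizes = np.array([(labels == k).sum() for k in range(K)])
        bgss = float((sizes * ((cents - mean) ** 2).sum(axis=1)).sum())
        wgss = float(
            sum(((vectors[labels == k] - cents[k]) ** 2).sum() for k in range(K))
        )
        ch = (bgss / (K - 1)) / (wgss / (n - K))
        scatter = np.array(
            [
                np.linalg.norm(vectors[labels == k] - cents[k], axis=1).mean()
                for k in range(K)
            ]
        )
        ratios = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                if i != j:
                    ratios[i, j] = (scatter[i] + scatter[j]) / np.linalg.norm(
                        cents[i] - cents[j]
                    )
        db = ratios.max(axis=1).mean()

        row = table.iloc[0]
        assert row["calinski_harabasz"] == pytest.approx(ch, rel=1e-9)
        assert row["davies_bouldin"] == pytest.approx(db, rel=1e-9)

    def test_degenerate_identical_vectors_rejected(self):
        with pytest.raises(DataError):
            dynfc.select_k(np.ones((20, 3)), k_range=[2])


class TestOrderStates:
    def _model(self, K, centroids=None):
        return dynfc.BrainStateModel(
            K=K,
            centroids=np.eye(K) if centroids is None else centroids,
            seed=0,
            restarts=1,
            inertia=0.0,
        )

    def test_descending_mean_kop(self):
        kop = np.array([0.8, 0.8, 0.3, 0.3, 0.3])
        labels = np.array([1, 1, 0, 0, 0])
        ordered = dynfc.order_states(self._model(2), kop, labels)
        assert list(ordered.state_order) == [1, 0]
        ranked = relabel_by_order(labels, ordered.state_order)
        assert list(ranked) == [0, 0, 1, 1, 1]

    def test_tie_broken_by_occupancy(self):
        kop = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        labels = np.array([0, 1, 1, 1, 0])
        ordered = dynfc.order_states(self._model(2), kop, labels)
        assert list(ordered.state_order) == [1, 0]

    def test_empty_states_sort_last(self):
        kop = np.array([0.2, 0.9])
        labels = np.array([0, 2])
        ordered = dynfc.order_states(self._model(3), kop, labels)
        assert list(ordered.state_order) == [2, 0, 1]

    def test_invariant_to_input_label_permutation(self, rng):
        kop = rng.uniform(0, 1, size=200)
        labels = rng.integers(0, 3, size=200)
        model = self._model(3, centroids=rng.standard_normal((3, 5)))
        ordered = dynfc.order_states(model, kop, labels)
        perm = np.array([2, 0, 1])  # relabel state k -> perm[k]
        model_p = self._model(3, centroids=model.centroids[np.argsort(perm)])
        ordered_p = dynfc.order_states(model_p, kop, perm[labels])
        final = model.centroids[ordered.state_order]
        final_p = model_p.centroids[ordered_p.state_order]
        assert np.allclose(final, final_p)
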