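"""Leading Eigenvector Dynamics Analysis (LEiDA).

Each fMRI volume is summarised by the P x P instantaneous phase-coherence
matrix ``M_ij(t) = cos(phi_i(t) - phi_j(t))`` and represented by the unit
eigenvector of its largest eigenvalue.  Cohort-pooled eigenvectors are
clustered with K-means; each cluster centroid is a recurrent "brain state"
and every volume is assigned the state of its nearest centroid.

Because ``cos(phi_i - phi_j) = cos(phi_i)cos(phi_j) + sin(phi_i)sin(phi_j)``,
the coherence matrix is exactly ``c c' + s s'`` with ``c = cos(phi)`` and
``s = sin(phi)``: a rank-2 positive semi-definite matrix.  The leading
eigenvector therefore lives in span{c, s} and is obtained from a 2 x 2
eigenproblem per volume, which makes whole-cohort extraction cheap.  The
generic dense route is kept for arbitrary symmetric matrices and serves as a
cross-check.

Eigenvector sign is ambiguous; vectors are oriented so that more than half
of the entries are non-positive (ties broken by making the largest-magnitude
entry negative), the convention under which clustering is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .phase import DataError, PhaseArray

__all__ = [
    "LeadingEigenvector",
    "BrainStateModel",
    "phase_coherence_matrix",
    "leading_eigenvector",
    "leida_vectors",
    "cluster_eigenvectors",
    "select_k",
    "order_states",
]


@dataclass
class LeadingEigenvector:
    """Unit-norm, sign-conventioned dominant eigenvector of a coherence matrix."""

    vector: np.ndarray
    eigenvalue: float


@dataclass
class BrainStateModel:
    """K-means brain-state model over pooled LEiDA vectors.

    ``centroids[k]`` is the direction of state ``k`` (0-based internal
    labels); ``state_order`` maps rank -> internal label once the states have
    been ordered by global synchrony (see :func:`order_states`).
    """

    K: int
    centroids: np.ndarray
    seed: int
    restarts: int
    inertia: float
    state_order: np.ndarray | None = None
    state_mean_kop: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def assign(self, vectors: np.ndarray) -> np.ndarray:
        """Nearest-centroid (squared Euclidean) state label per vector."""
        d2 = ((vectors[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def _orient(v: np.ndarray) -> np.ndarray:
    """Apply the majority-non-positive sign convention in place."""
    n_pos = int((v > 0).sum())
    n_neg = int((v < 0).sum())
    if n_pos > n_neg:
        return -v
    if n_pos == n_neg and v[np.argmax(np.abs(v))] > 0:
        return -v
    return v


def phase_coherence_matrix(phases_t: np.ndarray) -> np.ndarray:
    """Instantaneous phase-coherence matrix for one volume.

    Entry (i, j) is ``cos(phi_i - phi_j)``; the matrix is symmetric with a
    unit diagonal and entries in [-1, 1].
    """
    phases_t = np.asarray(phases_t, dtype=float)
    if phases_t.ndim != 1 or phases_t.size < 2:
        raise DataError("need a 1-D phase vector with at least 2 parcels")
    diff = phases_t[:, None] - phases_t[None, :]
    return np.cos(diff)


def leading_eigenvector(matrix: np.ndarray) -> LeadingEigenvector:
    """Dominant eigenpair of a symmetric matrix, sign-conventioned.

    Uses a dense symmetric eigendecomposition; suitable for any symmetric
    input, not only phase-coherence matrices.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise DataError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise DataError("matrix must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(matrix)
    vec = _orient(eigvecs[:, -1].copy())
    return LeadingEigenvector(vector=vec, eigenvalue=float(eigvals[-1]))


def leida_vectors(phases: PhaseArray) -> np.ndarray:
    """Leading eigenvector of the phase-coherence matrix at every volume.

    Exploits the rank-2 identity ``M(t) = c c' + s s'`` (c = cos phases,
    s = sin phases): the dominant eigenvector is a combination of c and s
    whose coefficients solve the 2 x 2 restriction ``G a = lambda a`` with
    G the Gram matrix of (c, s).  Output rows are unit norm and oriented by
    the majority-non-positive convention.
    """
    c = np.cos(phases.phases)  # (T', P)
    s = np.sin(phases.phases)
    # Gram matrices per volume
    cc = (c * c).sum(axis=1)
    ss = (s * s).sum(axis=1)
    cs = (c * s).sum(axis=1)
    # leading eigenvalue of [[cc, cs], [cs, ss]]
    half_tr = 0.5 * (cc + ss)
    disc = np.sqrt(np.maximum(0.25 * (cc - ss) ** 2 + cs**2, 0.0))
    lam = half_tr + disc
    # eigenvector (alpha, beta) of the 2x2; handle cs ~ 0 degenerate case
    alpha = np.where(np.abs(cs) > 1e-15, cs, np.where(cc >= ss, 1.0, 0.0))
    beta = np.where(np.abs(cs) > 1e-15, lam - cc, np.where(cc >= ss, 0.0, 1.0))
    vectors = alpha[:, None] * c + beta[:, None] * s
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    # degenerate volumes (norm ~ 0) fall back to the dense route
    bad = np.flatnonzero(norms[:, 0] < 1e-12)
    for t in bad:
        vectors[t] = leading_eigenvector(
            phase_coherence_matrix(phases.phases[t])
        ).vector
        norms[t, 0] = 1.0
    vectors /= norms
    for t in range(vectors.shape[0]):
        vectors[t] = _orient(vectors[t])
    return vectors


def cluster_eigenvectors(
    vectors: np.ndarray,
    K: int = 6,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[BrainStateModel, np.ndarray]:
    """K-means clustering of pooled LEiDA vectors into K brain states.

    Squared-Euclidean objective with k-means++ initialisation, best of
    ``restarts`` runs; deterministic for a fixed ``seed``.

    Returns
    -------
    model, labels
        The fitted :class:`BrainStateModel` and a 0-based state label for
        every input vector.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise DataError("vectors must be 2-D (n_volumes x P)")
    n_distinct = np.unique(vectors, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct vectors")
    if K < 1:
        raise ValueError("K must be >= 1")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    labels = km.fit_predict(vectors)
    model = BrainStateModel(
        K=K,
        centroids=km.cluster_centers_.copy(),
        seed=seed,
        restarts=restarts,
        inertia=float(km.inertia_),
    )
    return model, labels


def select_k(
    vectors: np.ndarray,
    k_range=range(2, 13),
    seed: int = 0,
    restarts: int = 20,
    subsample: int | None = None,
):
    """Clustering-quality table over candidate K.

    For each K the vectors are clustered as in :func:`cluster_eigenvectors`
    and the Calinski-Harabasz (higher = better separated) and Davies-Bouldin
    (lower = better) indices are reported.  No K is chosen automatically:
    the table supports the heuristic choice.

    ``subsample`` optionally caps the number of vectors used for the scan
    (without replacement, seeded); final state assignment never subsamples.
    """
    import pandas as pd

    vectors = np.asarray(vectors, dtype=float)
    if np.unique(vectors, axis=0).shape[0] < 2:
        raise DataError("all vectors identical; K selection is undefined")
    if subsample is not None and subsample < vectors.shape[0]:
        rng = np.random.default_rng(seed)
        idx = rng.choice(vectors.shape[0], size=subsample, replace=False)
        vectors = vectors[idx]
    rows = []
    for k in k_range:
        _, labels = cluster_eigenvectors(vectors, K=k, seed=seed, restarts=restarts)
        rows.append(
            {
                "K": k,
                "calinski_harabasz": calinski_harabasz_score(vectors, labels),
                "davies_bouldin": davies_bouldin_score(vectors, labels),
            }
        )
    return pd.DataFrame(rows)


def order_states(
    model: BrainStateModel,
    kop_values: np.ndarray,
    labels: np.ndarray,
) -> BrainStateModel:
    """Order states by descending pooled mean KOP (global synchrony).

    ``kop_values`` and ``labels`` are cohort-pooled and aligned per volume.
    Ties are broken by larger fractional occupancy; states with no assigned
    volumes sort last.  Returns a new model with ``state_order`` set such
    that ``state_order[rank] = internal label``; centroids are left in
    internal order.
    """
    kop_values = np.asarray(kop_values, dtype=float)
    labels = np.asarray(labels)
    if kop_values.shape[0] != labels.shape[0]:
        raise DataError("kop_values and labels must be aligned")
    K = model.K
    mean_kop = np.full(K, np.nan)
    occupancy = np.zeros(K)
    for k in range(K):
        sel = labels == k
        occupancy[k] = sel.mean()
        if sel.any():
            mean_kop[k] = kop_values[sel].mean()
    visited = ~np.isnan(mean_kop)
    # sort: visited first, then descending mean KOP, then descending occupancy
    key = np.lexsort((-occupancy, np.where(visited, -mean_kop, np.inf)))
    ordered = BrainStateModel(
        K=model.K,
        centroids=model.centroids,
        seed=model.seed,
        restarts=model.restarts,
        inertia=model.inertia,
        state_order=key.astype(int),
        state_mean_kop=mean_kop,
        metadata=dict(model.metadata),
    )
    return ordered


def relabel_by_order(labels: np.ndarray, state_order: np.ndarray) -> np.ndarray:
    """Map internal K-means labels to synchrony-rank labels (0 = most global)."""
    rank_of = np.empty_like(state_order)
    rank_of[state_order] = np.arange(state_order.size)
    return rank_of[labels]
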