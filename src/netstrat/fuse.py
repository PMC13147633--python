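"""Similarity Network Fusion (SNF) of patient-similarity layers.

Each data layer (here: hub-gene expression, circulating immune profile)
yields a patient affinity matrix from a scaled-exponential kernel on
Euclidean distances between z-scored feature vectors.  The layers are then
fused by iterative cross-diffusion: each layer's full transition kernel is
repeatedly propagated through the other layers' K-nearest-neighbour kernels
until the layers converge toward a single similarity matrix.  The number of
patient subtypes is picked by the eigengap of the normalised graph
Laplacian, and subtypes come from spectral clustering of the fused matrix.

The cross-diffusion scheme is implemented from scratch (it is the analytical
core of the integration step); k-means inside the spectral embedding uses
scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "AffinityMatrix",
    "FusedNetwork",
    "ClusterAssignment",
    "affinity_matrix",
    "snf_fuse",
    "eigengap_k",
    "spectral_cluster",
]


@dataclass
class AffinityMatrix:
    W: np.ndarray                   # N x N symmetric, nonnegative
    patient_ids: list[str]
    params: dict = field(default_factory=dict)


@dataclass
class FusedNetwork:
    P: np.ndarray                   # N x N fused similarity
    patient_ids: list[str]
    iterations_run: int
    layers: list[str]
    max_row_sum_deviation: float = 0.0


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    k: int
    eigengap_values: list[float] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


# ---------------------------------------------------------------------------
# affinity construction


def affinity_matrix(
    features: pd.DataFrame,
    K: int = 20,
    mu: float = 0.5,
    standardize: bool = True,
) -> AffinityMatrix:
    """Scaled-exponential affinity from a patients x variables table.

    W(i,j) = exp(-d(i,j)^2 / (mu * eps_ij)) with Euclidean d on per-variable
    z-scores and eps_ij the mean of: i's average distance to its K nearest
    neighbours, j's, and d(i,j).  K is capped at N-1; constant variables are
    dropped with a warning (they carry no between-patient signal and a zero
    variance breaks the z-score).
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, float))
    n = features.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 patients, got {n}")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dropped = [str(c) for c, s in zip(features.columns, sd) if s == 0]
        warnings.warn(
            f"dropping constant feature(s): {dropped}", stacklevel=2
        )
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    if standardize and X.shape[1]:
        X = (X - X.mean(axis=0)) / sd
    K = int(min(K, n - 1))
    d = squareform(pdist(X, metric="euclidean"))
    # mean distance to the K nearest neighbours (self excluded)
    sorted_d = np.sort(d, axis=1)[:, 1 : K + 1]
    mean_knn = sorted_d.mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + d) / 3.0
    eps = np.maximum(eps, np.finfo(float).tiny)
    W = np.exp(-(d**2) / (mu * eps))
    W = (W + W.T) / 2.0
    return AffinityMatrix(
        W=W,
        patient_ids=[str(i) for i in features.index],
        params={"K": K, "mu": mu, "standardize": standardize},
    )


# ---------------------------------------------------------------------------
# fusion


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-normalised transition kernel with half the mass on the diagonal:
    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k)) off-diagonal, 1/2 on it."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = off / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic kernel restricted to each row's K nearest neighbours."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    S = np.zeros_like(off)
    for i in range(n):
        idx = np.argsort(off[i])[::-1][:K]
        S[i, idx] = off[i, idx]
    rs = S.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return S / rs


def snf_fuse(
    affinities: list[AffinityMatrix],
    K: int = 20,
    t: int = 20,
) -> FusedNetwork:
    """Fuse two or more affinity layers by iterative cross-diffusion.

    Per layer v the full kernel P_v and the local K-NN kernel S_v are formed;
    each iteration updates P_v <- S_v @ mean(P_u, u != v) @ S_v.T followed by
    re-normalisation (half-mass diagonal), for ``t`` iterations.  The output
    is the symmetrised average of the final P_v.  A single layer is passed
    through its own diffusion with a warning.
    """
    if not affinities:
        raise ValueError("no affinity layers given")
    ids = affinities[0].patient_ids
    for a in affinities[1:]:
        if a.patient_ids != ids:
            raise ValueError(
                "affinity layers must share an identical, identically "
                f"ordered patient set; {a.patient_ids[:3]}... != {ids[:3]}..."
            )
    n = len(ids)
    K = int(min(K, n - 1))
    if len(affinities) == 1:
        warnings.warn(
            "single affinity layer: returning its diffused kernel", stacklevel=2
        )
    P = [_full_kernel(a.W) for a in affinities]
    S = [_knn_kernel(a.W, K) for a in affinities]
    m = len(P)
    max_dev = 0.0
    for _ in range(t):
        new = []
        for v in range(m):
            if m > 1:
                others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            else:
                others = P[v]
            Pv = S[v] @ others @ S[v].T
            # restore row-stochasticity with half-mass diagonal
            Pv = _full_kernel((Pv + Pv.T) / 2.0)
            new.append(Pv)
        P = new
        dev = max(float(np.abs(Pv.sum(axis=1) - 1.0).max()) for Pv in P)
        max_dev = max(max_dev, dev)
    fused = sum(P) / m
    fused = (fused + fused.T) / 2.0
    return FusedNetwork(
        P=fused,
        patient_ids=list(ids),
        iterations_run=t,
        layers=[str(a.params.get("layer", i)) for i, a in enumerate(affinities)],
        max_row_sum_deviation=max_dev,
    )


# ---------------------------------------------------------------------------
# model selection and clustering


def _normalized_laplacian_eigs(W: np.ndarray):
    W = np.asarray(W, float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("W must be square and symmetric")
    if (W < -1e-12).any():
        raise ValueError("W must be nonnegative")
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    dinv = 1.0 / np.sqrt(d)
    L = np.eye(W.shape[0]) - dinv[:, None] * W * dinv[None, :]
    L = (L + L.T) / 2.0
    vals, vecs = np.linalg.eigh(L)
    return vals, vecs


def eigengap_k(W: np.ndarray, k_min: int = 2, k_max: int = 5) -> tuple[int, list[float]]:
    """Cluster count maximising the eigengap of the normalised Laplacian.

    Eigenvalues are sorted ascending; the gap for candidate k is
    lambda_{k+1} - lambda_k and the argmax over [k_min, k_max] is returned
    together with the gap values.  If W has more connected components than
    k_max the spectrum cannot resolve them and k_max is returned with a
    warning.
    """
    vals, _ = _normalized_laplacian_eigs(W)
    n = len(vals)
    k_max = min(k_max, n - 1)
    n_zero = int(np.sum(vals < 1e-10))
    if n_zero > k_max:
        warnings.warn(
            f"{n_zero} connected components exceed k_max={k_max}", stacklevel=2
        )
        return k_max, []
    gaps = [float(vals[k] - vals[k - 1]) for k in range(k_min, k_max + 1)]
    k = int(k_min + int(np.argmax(gaps)))
    return k, gaps


def spectral_cluster(
    W,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    patient_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Normalised spectral clustering of a similarity matrix.

    Rows are embedded in the k eigenvectors of the symmetric normalised
    Laplacian with the smallest eigenvalues, row-normalised to the unit
    sphere, and clustered by k-means (k-means++ with ``restarts`` seeded
    initialisations, best inertia kept).  Deterministic under a fixed seed.
    """
    if isinstance(W, FusedNetwork):
        patient_ids = patient_ids or W.patient_ids
        W = W.P
    elif isinstance(W, AffinityMatrix):
        patient_ids = patient_ids or W.patient_ids
        W = W.W
    W = np.asarray(W, float)
    n = W.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]
    vals, vecs = _normalized_laplacian_eigs(W)
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    from sklearn.cluster import KMeans

    km = KMeans(
        n_clusters=k, n_init=restarts, random_state=int(seed) % (2**32 - 1)
    ).fit(U)
    raw = km.labels_
    # canonical label order: relabel by first appearance for determinism
    remap, nxt = {}, 0
    labels = []
    for l in raw:
        if l not in remap:
            remap[l] = nxt
            nxt += 1
        labels.append(remap[l])
    k_gap, gaps = eigengap_k(W, k_min=2, k_max=min(5, n - 1))
    return ClusterAssignment(
        labels=dict(zip(patient_ids, labels)), k=k, eigengap_values=gaps
    )
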