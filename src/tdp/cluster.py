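"""Gaussian DTW kernel and kernel k-means with seeded restarts.

The kernel is k_ij = exp(-d_ij^2 / (2 sigma^2)) with sigma defaulting
to the median off-diagonal DTW distance (median heuristic).  A Gaussian
of a DTW distance is not guaranteed positive semidefinite, so the
kernel is eigen-clipped (negative eigenvalues set to zero) by default.

Kernel k-means minimizes within-cluster dispersion in the implicit
feature space using only the kernel:

    dist^2(i, c) = k_ii - 2/|c| sum_{j in c} k_ij + 1/|c|^2 sum_{j,l in c} k_jl

Initialization is kernel k-means++; ties in assignment break toward the
lowest cluster index; empty clusters are repaired by moving in the
point currently farthest from its center.  The best of ``n_restarts``
seeded restarts (by objective) is returned, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tdp.dtw import DistanceMatrix


@dataclass
class KernelMatrix:
    ids: list
    values: np.ndarray
    sigma: float
    psd_repaired: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterSolution:
    """One kernel k-means fit at a fixed K."""

    K: int
    labels: np.ndarray
    objective: float
    medoid_ids: list = field(default_factory=list)
    medoid_indices: np.ndarray | None = None
    n_iter: int = 0
    restart_index: int = 0
    seed: int = 0
    ids: list = field(default_factory=list)


def build_kernel(dist: DistanceMatrix, sigma: float | None = None,
                 psd_repair: bool = True) -> KernelMatrix:
    """Gaussian kernel of a DTW distance matrix with optional PSD repair."""
    D = dist.values
    n = D.shape[0]
    if sigma is None:
        off = D[np.triu_indices(n, k=1)]
        sigma = float(np.median(off))
        if sigma <= 0:
            raise ValueError("median off-diagonal distance is 0; pass an explicit sigma")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    K = np.exp(-(D ** 2) / (2.0 * sigma ** 2))
    repaired = False
    if psd_repair:
        w, V = np.linalg.eigh(K)
        if w[0] < 0:
            w = np.clip(w, 0.0, None)
            K = (V * w) @ V.T
            K = (K + K.T) / 2.0
            repaired = True
    return KernelMatrix(ids=list(dist.ids), values=K, sigma=sigma, psd_repaired=repaired)


def _point_dist2(K: np.ndarray, centers: list[int]) -> np.ndarray:
    """Feature-space squared distances of every point to single-point
    centers (used by the k-means++ seeding)."""
    kd = np.diag(K)
    return kd[:, None] + kd[None, centers] - 2.0 * K[:, centers]


def _kmeanspp(K: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = K.shape[0]
    centers = [int(rng.integers(n))]
    for _ in range(k - 1):
        d2 = _point_dist2(K, centers).min(axis=1)
        d2 = np.clip(d2, 0.0, None)
        total = d2.sum()
        if total <= 0:
            centers.append(int(rng.integers(n)))
            continue
        centers.append(int(rng.choice(n, p=d2 / total)))
    return _point_dist2(K, centers).argmin(axis=1)


def _cluster_dist2(K: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """n x k matrix of feature-space squared distances to cluster means."""
    n = K.shape[0]
    H = np.zeros((n, k))
    H[np.arange(n), labels] = 1.0
    sizes = H.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("empty cluster in distance computation")
    Hn = H / sizes
    cross = K @ Hn                      # (1/|c|) sum_{j in c} k_ij
    quad = np.einsum("ic,ic->c", Hn, K @ Hn)  # (1/|c|^2) sum_{j,l in c} k_jl
    return np.diag(K)[:, None] - 2.0 * cross + quad[None, :]


def kernel_kmeans(kernel: KernelMatrix, K: int, seed: int = 0,
                  n_restarts: int = 20, max_iter: int = 100) -> ClusterSolution:
    """Best-of-restarts kernel k-means; deterministic given ``seed``."""
    Km = kernel.values
    n = Km.shape[0]
    if not np.isfinite(Km).all():
        raise ValueError("kernel contains non-finite entries")
    if not 2 <= K <= n:
        raise ValueError(f"K={K} out of range [2, {n}]")
    rng = np.random.default_rng(seed)
    best: ClusterSolution | None = None
    for r in range(n_restarts):
        labels = _kmeanspp(Km, K, rng)
        labels = _repair_empty(Km, labels, K)
        prev_obj = np.inf
        n_iter = 0
        for it in range(max_iter):
            d2 = _cluster_dist2(Km, labels, K)
            new_labels = d2.argmin(axis=1)  # argmin ties -> lowest index
            new_labels = _repair_empty(Km, new_labels, K)
            obj = float(_cluster_dist2(Km, new_labels, K)[np.arange(n), new_labels].sum())
            # objective is non-increasing on a PSD kernel
            if obj > prev_obj + 1e-8 * max(1.0, abs(prev_obj)):
                raise AssertionError(f"kernel k-means objective increased: {prev_obj} -> {obj}")
            n_iter = it + 1
            if np.array_equal(new_labels, labels):
                labels = new_labels
                prev_obj = obj
                break
            labels = new_labels
            prev_obj = obj
        if best is None or prev_obj < best.objective:
            best = ClusterSolution(K=K, labels=labels.copy(), objective=prev_obj,
                                   n_iter=n_iter, restart_index=r, seed=seed,
                                   ids=list(kernel.ids))
    assert best is not None
    return best


def _repair_empty(K: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Move the globally farthest point into each empty cluster."""
    labels = labels.copy()
    n = labels.size
    for c in range(k):
        if (labels == c).any():
            continue
        occupied = [cc for cc in range(k) if (labels == cc).any()]
        # distances to currently occupied clusters only
        n_occ = np.zeros((n, len(occupied)))
        for a, cc in enumerate(occupied):
            n_occ[:, a] = _cluster_dist2_single(K, labels, cc)
        own = n_occ[np.arange(n), [occupied.index(int(labels[i])) for i in range(n)]]
        # avoid emptying a singleton cluster
        sizes = np.bincount(labels, minlength=k)
        own[sizes[labels] <= 1] = -np.inf
        labels[int(own.argmax())] = c
    return labels


def _cluster_dist2_single(K: np.ndarray, labels: np.ndarray, c: int) -> np.ndarray:
    members = np.flatnonzero(labels == c)
    cross = K[:, members].mean(axis=1)
    quad = K[np.ix_(members, members)].mean()
    return np.diag(K) - 2.0 * cross + quad


def compute_medoids(dist: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-cluster medoid indices: minimizers of total within-cluster
    DTW distance (lowest index on ties)."""
    labels = np.asarray(labels)
    out = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        sub = dist.values[np.ix_(members, members)]
        out.append(int(members[sub.sum(axis=1).argmin()]))
    return np.asarray(out)


def cluster_profiles(dist: DistanceMatrix, K: int, seed: int = 0,
                     n_restarts: int = 20, max_iter: int = 100,
                     sigma: float | None = None, psd_repair: bool = True,
                     kernel: KernelMatrix | None = None) -> ClusterSolution:
    """DTW distances -> Gaussian kernel -> kernel k-means -> medoids."""
    if kernel is None:
        kernel = build_kernel(dist, sigma=sigma, psd_repair=psd_repair)
    sol = kernel_kmeans(kernel, K, seed=seed, n_restarts=n_restarts, max_iter=max_iter)
    sol.medoid_indices = compute_medoids(dist, sol.labels)
    sol.medoid_ids = [dist.ids[i] for i in sol.medoid_indices]
    return sol
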