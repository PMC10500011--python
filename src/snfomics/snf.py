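"""Similarity network fusion: per-layer affinity graphs, cross-network
diffusion, spectral clustering, eigengap model selection, network export.

The affinity kernel follows the scaled exponential Euclidean kernel of the
cross-diffusion fusion literature: for samples i, j at distance ``d_ij``
(Euclidean over z-scored features),

    W_ij = exp(-d_ij^2 / (mu * eps_ij)),
    eps_ij = (mean_K(i) + mean_K(j) + d_ij) / 3,

where ``mean_K(i)`` is the mean distance of i to its K nearest other
samples. Two row-normalised operators drive the diffusion: the full kernel
``P`` (off-diagonal mass 1/2, diagonal exactly 1/2) and the sparse
K-nearest-neighbour kernel ``S`` (each row supported on the sample itself
plus its K nearest others). Fusion iterates, for layer v,

    H_v <- S_v @ mean_{w != v}(P_w) @ S_v^T,

re-normalises every round to the P convention, and averages the final
status matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .io import OmicMatrix
from .preprocess import log_and_zscore

logger = logging.getLogger(__name__)

__all__ = [
    "SNFParams",
    "AffinityMatrix",
    "FusionResult",
    "build_affinity",
    "fuse_networks",
    "spectral_cluster",
    "estimate_num_clusters",
    "export_network",
]


@dataclass
class SNFParams:
    """Fusion hyperparameters: K nearest neighbours, kernel scale mu, and
    diffusion iterations T (defaults K=10, mu=0.5, T=10)."""

    K: int = 10
    mu: float = 0.5
    T: int = 10

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not 0.3 <= self.mu <= 0.8:
            warnings.warn(f"mu={self.mu} outside the recommended [0.3, 0.8] range", stacklevel=2)


@dataclass
class AffinityMatrix:
    """A layer's sample-affinity kernel with its normalised operators."""

    sample_ids: list[str]
    W: np.ndarray
    P: np.ndarray
    S: np.ndarray
    layer_name: str = ""


@dataclass
class FusionResult:
    sample_ids: list[str]
    fused: np.ndarray
    per_layer: list[AffinityMatrix]
    trace: list[float] = field(default_factory=list)
    labels: np.ndarray | None = None
    eigengaps: np.ndarray | None = None


def _normalize_p(W: np.ndarray) -> np.ndarray:
    """Row-normalise to the P convention: off-diagonal rows sum to 1/2,
    diagonal exactly 1/2 (so full rows sum to 1)."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    P = off / (2.0 * rowsum)
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, D: np.ndarray, K: int, order: np.ndarray) -> np.ndarray:
    """Sparse row-stochastic kernel supported on self + K nearest others.

    ``order`` gives, per row, the other samples sorted by (distance,
    sample index) so distance ties break deterministically by sample order.
    """
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        nbrs = order[i, :K]
        idx = np.concatenate(([i], nbrs))
        vals = W[i, idx]
        S[i, idx] = vals / vals.sum()
    return S


def build_affinity(matrix: OmicMatrix, params: SNFParams | None = None) -> AffinityMatrix:
    """Scaled exponential Euclidean affinity of one layer.

    Features are z-scored (population sd) before computing pairwise
    Euclidean distances. Missing values are not accepted.
    """
    params = params or SNFParams()
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    if params.K >= n:
        raise ValueError(f"K={params.K} must be smaller than the number of samples ({n})")
    if matrix.values.isna().any().any():
        raise ValueError("missing values are not allowed; filter or impute upstream")

    Z = log_and_zscore(matrix).values.to_numpy()
    D = squareform(pdist(Z.T, metric="euclidean"))

    # per-row neighbour order over other samples; ties by sample index
    D_off = D.copy()
    np.fill_diagonal(D_off, np.inf)
    order = np.argsort(D_off, axis=1, kind="stable")[:, : n - 1]
    mean_k = np.take_along_axis(D, order[:, : params.K], axis=1).mean(axis=1)
    eps = (mean_k[:, None] + mean_k[None, :] + D) / 3.0
    W = np.exp(-(D**2) / (params.mu * eps + 1e-300))
    np.fill_diagonal(W, 1.0)
    W = (W + W.T) / 2.0

    P = _normalize_p(W)
    S = _knn_kernel(W, D, params.K, order)
    return AffinityMatrix(sample_ids=list(matrix.sample_ids), W=W, P=P, S=S, layer_name=matrix.layer_name)


def fuse_networks(affinities: list[AffinityMatrix], params: SNFParams | None = None) -> FusionResult:
    """Cross-network diffusion over >= 1 layers on an identical sample set.

    A single layer is passed through as its own P operator so single-omic
    comparisons run with the same interface. ``T=0`` returns the plain
    average of the layers' P matrices.
    """
    params = params or SNFParams()
    if not affinities:
        raise ValueError("need at least one affinity matrix")
    ids = affinities[0].sample_ids
    for a in affinities[1:]:
        if a.sample_ids != ids:
            raise ValueError("all layers must share an identical sample set and order")

    if len(affinities) == 1:
        fused = affinities[0].P.copy()
        fused = (fused + fused.T) / 2.0
        return FusionResult(sample_ids=ids, fused=fused, per_layer=list(affinities))

    status = [a.P.copy() for a in affinities]
    trace: list[float] = []
    for _ in range(params.T):
        new_status = []
        for v, a in enumerate(affinities):
            others = [status[w] for w in range(len(status)) if w != v]
            avg = np.mean(others, axis=0)
            H = a.S @ avg @ a.S.T
            H = _normalize_p((H + H.T) / 2.0)
            new_status.append(H)
        trace.append(float(np.mean([np.linalg.norm(n_ - o_) for n_, o_ in zip(new_status, status)])))
        status = new_status
    fused = np.mean(status, axis=0)
    fused = (fused + fused.T) / 2.0
    return FusionResult(sample_ids=ids, fused=fused, per_layer=list(affinities), trace=trace)


def _normalized_laplacian_eigh(W: np.ndarray):
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(W.shape[0]) - d_inv_sqrt[:, None] * W * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    return np.linalg.eigh(L)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0,1,... in order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def spectral_cluster(fused: np.ndarray, k: int, seed: int = 0, n_restarts: int = 50) -> np.ndarray:
    """Normalised spectral clustering of a symmetric non-negative similarity.

    Embeds samples with the k bottom eigenvectors of the symmetric
    normalised Laplacian, unit-normalises rows, and runs k-means with
    ``n_restarts`` seeded restarts. Labels are canonicalised by first
    occurrence, so the output is deterministic given the seed.
    """
    fused = np.asarray(fused, dtype=float)
    n = fused.shape[0]
    if fused.shape != (n, n) or not np.allclose(fused, fused.T, atol=1e-8):
        raise ValueError("similarity must be a symmetric square matrix")
    if np.min(fused) < -1e-12:
        raise ValueError("similarity must be non-negative")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        return np.arange(n)

    n_comp, _ = connected_components((fused > 0).astype(int), directed=False)
    if n_comp > k:
        warnings.warn(
            f"graph has {n_comp} connected components but k={k}; assignment is deterministic but arbitrary across components",
            stacklevel=2,
        )

    eigvals, eigvecs = _normalized_laplacian_eigh(fused)
    U = eigvecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**32))
    labels = km.fit_predict(U)
    return _canonical_labels(labels)


def estimate_num_clusters(fused: np.ndarray, k_max: int = 6) -> tuple[int, np.ndarray]:
    """Eigengap model selection on the normalised Laplacian spectrum.

    Returns ``(best_k, gaps)`` where ``gaps[i]`` is the eigengap for
    ``k = i + 2`` (the gap between the k-th and (k+1)-th smallest
    eigenvalues). Ties break toward the smallest k.
    """
    n = fused.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of samples")
    eigvals, _ = _normalized_laplacian_eigh(fused)
    ks = np.arange(2, k_max + 1)
    gaps = eigvals[ks] - eigvals[ks - 1]
    best_k = int(ks[np.argmax(gaps)])  # argmax returns the first max: smallest k wins ties
    return best_k, gaps


def export_network(fused: np.ndarray, sample_ids: list[str], path=None) -> pd.DataFrame:
    """Minimal high-similarity edge list covering every sample.

    Edges are scanned in order of descending similarity (ties by index
    pair) and retained only when they touch a not-yet-covered sample, until
    every sample has degree >= 1. Written as a 3-column tab-separated list
    (source, target, weight) when ``path`` is given.
    """
    fused = np.asarray(fused, dtype=float)
    if not np.allclose(fused, fused.T, atol=1e-8):
        raise ValueError("similarity must be symmetric")
    n = fused.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, -fused[iu, ju]))
    covered = np.zeros(n, dtype=bool)
    rows = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        if covered[i] and covered[j]:
            continue
        rows.append((sample_ids[i], sample_ids[j], fused[i, j]))
        covered[i] = covered[j] = True
        if covered.all():
            break
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    if path is not None:
        edges.to_csv(path, sep="\t", index=False)
    return edges
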