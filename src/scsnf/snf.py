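"""Similarity Network Fusion (SNF).

Builds a per-modality patient-similarity network from a scaled exponential
kernel on Euclidean distances, then fuses the networks by iterative
cross-diffusion: each modality's full-normalized status matrix is updated
through its own K-nearest-neighbour transition matrix against the average
of the other modalities' status matrices.  The fused network is the average
of the final status matrices.

Notation, for a distance matrix D on n subjects:

* kernel  ``W(i,j) = exp(-d(i,j)^2 / (2 * (mu * eps(i,j))^2))`` with the
  adaptive bandwidth
  ``eps(i,j) = (mean_k d(i,N_k(i)) + mean_k d(j,N_k(j)) + d(i,j)) / 3``
  (the Gaussian-density form used by the fusion method's reference
  implementation; the manuscript-style variant that divides by
  ``mu * eps`` un-squared has a distance-scaled exponent and collapses
  onto single nearest neighbours in high dimension),
* full normalization ``P``: ``P(i,i) = 1/2`` and
  ``P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k))`` for ``j != i``,
* kNN normalization ``S``: row-stochastic restriction of ``W`` to each
  subject's K nearest neighbours (self excluded),
* diffusion ``P_v <- S_v @ mean_{u != v}(P_u) @ S_v^T`` for T iterations,
  re-symmetrizing and restoring the P-form (diagonal 1/2) after each step.

Variants of the diagonal handling exist in the literature; the P-form
restoration used here keeps every status matrix row-stochastic up to the
fixed 1/2 diagonal, which makes the diffusion a proper random-walk
smoothing at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import MultiOmicsDataset, OmicsBlock


@dataclass
class SNFParams:
    """Fusion hyperparameters.

    K_nn
        Neighbourhood size for both the kernel bandwidth and the kNN
        transition matrix. Must be smaller than the number of subjects.
    mu
        Kernel bandwidth scale; larger values give flatter similarities.
        Recommended range 0.3-0.8.
    T
        Number of cross-diffusion iterations.
    """

    K_nn: int = 20
    mu: float = 0.5
    T: int = 20

    def __post_init__(self) -> None:
        if self.K_nn < 1:
            raise ValueError("K_nn must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class FusedNetwork:
    """Fused subject-similarity matrix with provenance."""

    matrix: np.ndarray
    subject_ids: list[str]
    modalities: list[str] = field(default_factory=list)
    params: SNFParams | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("fused matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("fused matrix must be symmetric")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("fused matrix must be finite and nonnegative")
        if np.any(np.diag(m) <= 0):
            raise ValueError("fused matrix must have strictly positive diagonal")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.subject_ids, columns=self.subject_ids)


def pairwise_distance(block: OmicsBlock | np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between subjects (rows)."""
    X = block.values if isinstance(block, OmicsBlock) else np.asarray(block, dtype=float)
    if X.size == 0:
        raise ValueError("empty block")
    return squareform(pdist(X, metric="euclidean"))


def affinity_from_distance(D: np.ndarray, params: SNFParams) -> np.ndarray:
    """Scaled exponential similarity kernel W from a distance matrix.

    ``W(i,j) = exp(-d(i,j)^2 / (2 * (mu * eps(i,j))^2))`` with the locally
    adaptive bandwidth ``eps`` averaging the two subjects' mean distances
    to their K nearest neighbours and their own distance.  ``W(i,i) = 1``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if params.K_nn >= n:
        raise ValueError(f"K_nn={params.K_nn} must be < n={n}")
    # mean distance to the K nearest neighbours, self (zero) excluded
    knn_mean = np.sort(D, axis=1)[:, 1 : params.K_nn + 1].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + D) / 3.0
    if np.any(eps <= 0):
        raise ValueError(
            "zero kernel bandwidth: some subjects are identical across all "
            "features; remove duplicates or add jitter"
        )
    W = np.exp(-(D**2) / (2.0 * (params.mu * eps) ** 2))
    return (W + W.T) / 2.0


def full_normalize(W: np.ndarray) -> np.ndarray:
    """Full (global) normalization P: diagonal 1/2, off-diagonal mass halved."""
    W = np.asarray(W, dtype=float)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    if np.any(rowsum <= 0):
        bad = int(np.flatnonzero(rowsum <= 0)[0])
        raise ValueError(f"row {bad} of W has zero off-diagonal mass")
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def knn_normalize(W: np.ndarray, K_nn: int) -> np.ndarray:
    """Row-stochastic restriction of W to each row's K nearest neighbours."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if K_nn >= n:
        raise ValueError(f"K_nn={K_nn} must be < n={n}")
    off = W.copy()
    np.fill_diagonal(off, -np.inf)  # self never a neighbour
    # indices of the K largest similarities per row (ties by lower index)
    order = np.argsort(-off, axis=1, kind="stable")[:, :K_nn]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), K_nn)
    S[rows, order.ravel()] = W[rows, order.ravel()]
    rowsum = S.sum(axis=1)
    if np.any(rowsum <= 0):
        bad = int(np.flatnonzero(rowsum <= 0)[0])
        raise ValueError(f"row {bad} of W has zero mass on its K_nn neighbours")
    return S / rowsum[:, None]


def snf_fuse(
    blocks_P: list[np.ndarray],
    blocks_S: list[np.ndarray],
    params: SNFParams,
    subject_ids: list[str] | None = None,
    modalities: list[str] | None = None,
) -> FusedNetwork:
    """Cross-diffusion fusion of >= 2 modalities' (P, S) matrix pairs."""
    v = len(blocks_P)
    if v < 2 or len(blocks_S) != v:
        raise ValueError("need matching P and S lists for >= 2 modalities")
    n = blocks_P[0].shape[0]
    for M in list(blocks_P) + list(blocks_S):
        if M.shape != (n, n):
            raise ValueError("dimension mismatch across modalities")
    status = [np.array(P, dtype=float) for P in blocks_P]
    for _ in range(params.T):
        updated = []
        for i in range(v):
            others = (sum(status) - status[i]) / (v - 1)
            M = blocks_S[i] @ others @ blocks_S[i].T
            M = (M + M.T) / 2.0
            updated.append(full_normalize(M))
        status = updated
    fused = sum(status) / v
    fused = (fused + fused.T) / 2.0
    if subject_ids is None:
        subject_ids = [str(i) for i in range(n)]
    return FusedNetwork(fused, list(subject_ids), list(modalities or []), params)


def fuse_dataset(dataset: MultiOmicsDataset, params: SNFParams | None = None) -> FusedNetwork:
    """Convenience path: standardized blocks -> kernels -> fused network."""
    params = params or SNFParams()
    Ps, Ss = [], []
    for block in dataset.blocks.values():
        W = affinity_from_distance(pairwise_distance(block), params)
        Ps.append(full_normalize(W))
        Ss.append(knn_normalize(W, params.K_nn))
    return snf_fuse(Ps, Ss, params, dataset.subject_ids, dataset.modalities)
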