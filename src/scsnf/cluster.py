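"""Spectral clustering, consensus clustering, model selection and agreement.

The clustering engine treats any symmetric nonnegative matrix as an
affinity.  Spectral clustering embeds subjects with the bottom eigenvectors
of the symmetric-normalized graph Laplacian and partitions the
row-normalized embedding with seeded k-means.  Consensus clustering
repeats this on random subject subsamples and records how often each pair
of subjects lands in the same cluster; the consensus-proportion matrix is
itself an affinity, and the final labels come from spectral-clustering it.

Model selection follows the average-silhouette rule: for each candidate k
the silhouette is computed on the dissimilarity 1 - consensus(i, j) of that
k's own consensus run, and the k with the largest mean silhouette wins
(ties to the smaller k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score, silhouette_score

from ._utils import logger, small_seed
from .io import MultiOmicsDataset
from .snf import SNFParams, affinity_from_distance, pairwise_distance

KMEANS_RESTARTS = 25


@dataclass
class ClusterAssignment:
    """Cluster labels in 1..k, canonicalized for stable reporting.

    Cluster 1 is the cluster containing the lexicographically smallest
    subject ID; cluster 2 the one containing the smallest ID not yet
    covered, and so on.
    """

    labels: np.ndarray
    k: int
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.subject_ids:
            self.subject_ids = [str(i) for i in range(len(self.labels))]

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.subject_ids, name="subtype")

    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering proportions over subsampled runs."""

    proportion: np.ndarray
    cosample_counts: np.ndarray
    iterations: int
    subsample_ratio: float
    subject_ids: list[str] = field(default_factory=list)


@dataclass
class SilhouetteProfile:
    """Mean silhouette per candidate k (consensus dissimilarity)."""

    scores: dict[int, float]

    def select_k(self) -> int:
        best = max(self.scores.values())
        return min(k for k, s in self.scores.items() if s == best)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, name="mean_silhouette").rename_axis("k")


def _canonicalize(labels: np.ndarray, subject_ids: list[str]) -> np.ndarray:
    order = np.argsort(np.asarray(subject_ids, dtype=object))
    mapping: dict[int, int] = {}
    nxt = 1
    for i in order:
        lab = int(labels[i])
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
    return np.array([mapping[int(l)] for l in labels], dtype=int)


def spectral_cluster(
    W: np.ndarray, k: int, seed: int = 0, subject_ids: list[str] | None = None
) -> ClusterAssignment:
    """Normalized-cut spectral clustering of an affinity matrix.

    Uses the k eigenvectors of smallest eigenvalue of
    ``L_sym = I - D^{-1/2} W D^{-1/2}``, row-normalizes the embedding and
    partitions it with k-means (25 seeded restarts).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n; got k={k}, n={n}")
    deg = W.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)  # isolated subjects: unit degree
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    U = vecs / norms[:, None]
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed & 0x7FFFFFFF)
    raw = km.fit_predict(U) + 1
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)]
    return ClusterAssignment(_canonicalize(raw, ids), k, ids)


def consensus_cluster(
    W: np.ndarray,
    k: int,
    iterations: int = 100,
    ratio: float = 0.8,
    seed: int = 0,
    subject_ids: list[str] | None = None,
) -> tuple[ConsensusMatrix, ClusterAssignment]:
    """Consensus clustering by subsampled spectral runs.

    Each iteration draws ``floor(ratio * n)`` subjects without replacement,
    spectral-clusters the restricted affinity and accumulates co-cluster /
    co-sample counts.  Final labels are the spectral clustering of the
    consensus-proportion matrix at the same k.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (0 < ratio <= 1):
        raise ValueError("subsample ratio must be in (0, 1]")
    m = int(np.floor(ratio * n))
    if not (2 <= k < m):
        raise ValueError(f"k={k} must satisfy 2 <= k < subsample size {m}")
    rng = np.random.default_rng(small_seed(seed, "consensus", k, iterations))
    cocluster = np.zeros((n, n))
    cosample = np.zeros((n, n))
    for it in range(iterations):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = W[np.ix_(idx, idx)]
        asg = spectral_cluster(sub, k, seed=small_seed(seed, "iter", it))
        cosample[np.ix_(idx, idx)] += 1.0
        same = asg.labels[:, None] == asg.labels[None, :]
        cocluster[np.ix_(idx, idx)] += same
    if np.any(cosample == 0):
        raise ValueError(
            "some subject pair was never co-sampled; increase iterations"
        )
    proportion = cocluster / cosample
    proportion = (proportion + proportion.T) / 2.0
    np.fill_diagonal(proportion, 1.0)
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)]
    consensus = ConsensusMatrix(proportion, cosample, iterations, ratio, ids)
    final = spectral_cluster(proportion, k, seed=small_seed(seed, "final", k), subject_ids=ids)
    return consensus, final


def silhouette_profile(
    W: np.ndarray,
    k_range: range = range(2, 11),
    iterations: int = 100,
    ratio: float = 0.8,
    seed: int = 0,
    subject_ids: list[str] | None = None,
) -> tuple[SilhouetteProfile, dict[int, tuple[ConsensusMatrix, ClusterAssignment]]]:
    """Mean silhouette per k, each on its own consensus run.

    Returns the profile and the per-k (consensus, labels) pairs so the
    selected k's results can be reused without recomputation.
    """
    n = np.asarray(W).shape[0]
    ks = [k for k in k_range]
    if not ks or ks[0] < 2 or ks[-1] >= n:
        raise ValueError(f"k_range must lie within [2, n-1]; got {ks} for n={n}")
    scores: dict[int, float] = {}
    runs: dict[int, tuple[ConsensusMatrix, ClusterAssignment]] = {}
    for k in ks:
        consensus, labels = consensus_cluster(W, k, iterations, ratio, seed, subject_ids)
        D = 1.0 - consensus.proportion
        np.fill_diagonal(D, 0.0)
        D = np.clip(D, 0.0, None)
        if len(np.unique(labels.labels)) < 2:
            scores[k] = 0.0
        else:
            scores[k] = float(silhouette_score(D, labels.labels, metric="precomputed"))
        runs[k] = (consensus, labels)
        logger.debug("silhouette k=%d -> %.4f", k, scores[k])
    return SilhouetteProfile(scores), runs


def select_k(profile: SilhouetteProfile) -> int:
    return profile.select_k()


def nmi(a: ClusterAssignment | np.ndarray, b: ClusterAssignment | np.ndarray) -> float:
    """Normalized mutual information, geometric-mean normalization.

    Both labelings single-cluster is perfect (vacuous) agreement: 1.0.
    """
    la = a.labels if isinstance(a, ClusterAssignment) else np.asarray(a)
    lb = b.labels if isinstance(b, ClusterAssignment) else np.asarray(b)
    if len(la) != len(lb):
        raise ValueError("labelings cover different subject sets")
    if len(np.unique(la)) == 1 and len(np.unique(lb)) == 1:
        return 1.0
    return float(normalized_mutual_info_score(la, lb, average_method="geometric"))


def match_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Relabel ``b`` to maximally agree with ``a`` (optimal assignment)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    conf = np.zeros((len(ub), len(ua)))
    for i, x in enumerate(ub):
        for j, y in enumerate(ua):
            conf[i, j] = np.sum((b == x) & (a == y))
    rows, cols = linear_sum_assignment(-conf)
    mapping = {int(ub[r]): int(ua[c]) for r, c in zip(rows, cols)}
    spare = [int(x) for x in ub if int(x) not in mapping]
    unused = [int(x) for x in np.arange(1, len(ub) + len(ua) + 1) if x not in mapping.values()]
    for x, y in zip(spare, unused):
        mapping[x] = y
    return np.array([mapping[int(x)] for x in b], dtype=int)


def modality_contribution(
    dataset: MultiOmicsDataset,
    fused_labels: ClusterAssignment,
    params: SNFParams | None = None,
    iterations: int = 100,
    ratio: float = 0.8,
    seed: int = 0,
) -> dict[str, float]:
    """NMI between each single-modality consensus clustering and the fused labels.

    Each modality's standardized block gets its own kernel affinity and the
    same consensus clustering at the fused solution's k.
    """
    params = params or SNFParams()
    k = fused_labels.k
    out: dict[str, float] = {}
    for name, block in dataset.blocks.items():
        W = affinity_from_distance(pairwise_distance(block), params)
        _, labels = consensus_cluster(
            W, k, iterations, ratio, seed=small_seed(seed, "contrib", name),
            subject_ids=dataset.subject_ids,
        )
        out[name] = nmi(labels, fused_labels)
    return out
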