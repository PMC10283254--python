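"""Model/Results interface for multi-omics subtyping.

:class:`MultiOmicsSubtypeModel` bundles the full unsupervised procedure —
per-modality preprocessing, similarity-network fusion, consensus spectral
clustering, silhouette model selection — behind a statsmodels-style
``fit()`` that returns a :class:`SubtypeResults` object carrying the fused
network, the selected k, stable subtype labels, the silhouette profile and
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from .cluster import ClusterAssignment, ConsensusMatrix, SilhouetteProfile
from .io import MultiOmicsDataset, OmicsBlock, align_subjects, standardize_features, variance_filter
from .snf import FusedNetwork, SNFParams, fuse_dataset


class MultiOmicsSubtypeModel:
    """Subtype discovery model over a multi-omics dataset.

    Parameters
    ----------
    dataset : MultiOmicsDataset
        Aligned, variance-filtered, standardized blocks (use
        :meth:`from_blocks` to go from raw blocks).
    snf_params : SNFParams
        Fusion hyperparameters.
    k_range : range
        Candidate cluster counts for silhouette model selection.
    consensus_iterations, subsample_ratio
        Consensus-clustering settings (defaults 100 and 0.8).
    """

    def __init__(
        self,
        dataset: MultiOmicsDataset,
        snf_params: SNFParams | None = None,
        k_range: range = range(2, 11),
        consensus_iterations: int = 100,
        subsample_ratio: float = 0.8,
    ) -> None:
        self.dataset = dataset
        self.snf_params = snf_params or SNFParams()
        self.k_range = k_range
        self.consensus_iterations = consensus_iterations
        self.subsample_ratio = subsample_ratio

    @classmethod
    def from_blocks(
        cls,
        blocks: list[OmicsBlock],
        variance_filters: dict[str, float] | None = None,
        **kwargs,
    ) -> "MultiOmicsSubtypeModel":
        """Build a model from raw blocks: align, filter, standardize.

        ``variance_filters`` maps modality -> top-variance fraction; by
        default only the toRNA block is filtered, to its top 10% most
        variable features.
        """
        if variance_filters is None:
            variance_filters = {"torna": 0.10}
        dataset = align_subjects(blocks)
        prepped = []
        for name, block in dataset.blocks.items():
            q = variance_filters.get(name, 1.0)
            if q < 1.0:
                block = variance_filter(block, q)
            prepped.append(standardize_features(block))
        return cls(MultiOmicsDataset({b.modality: b for b in prepped}, dataset.subject_ids), **kwargs)

    def fit(self, seed: int = 0, k: int | None = None) -> "SubtypeResults":
        """Fuse, select k by mean silhouette (unless fixed), and label subjects."""
        fused = fuse_dataset(self.dataset, self.snf_params)
        if k is not None:
            consensus, labels = _cluster.consensus_cluster(
                fused.matrix, k, self.consensus_iterations, self.subsample_ratio,
                seed, self.dataset.subject_ids,
            )
            profile = SilhouetteProfile({k: np.nan})
            runs = {k: (consensus, labels)}
        else:
            profile, runs = _cluster.silhouette_profile(
                fused.matrix, self.k_range, self.consensus_iterations,
                self.subsample_ratio, seed, self.dataset.subject_ids,
            )
            k = profile.select_k()
            consensus, labels = runs[k]
        return SubtypeResults(self, fused, k, labels, consensus, profile, seed)


@dataclass
class SubtypeResults:
    """Fitted subtyping results.

    Attributes
    ----------
    fused : FusedNetwork
        The cross-diffused similarity network.
    k : int
        Selected (or fixed) number of subtypes.
    assignment : ClusterAssignment
        Canonicalized subtype labels.
    consensus : ConsensusMatrix
        Co-clustering proportions at the selected k.
    silhouette : SilhouetteProfile
        Mean silhouette per candidate k.
    """

    model: MultiOmicsSubtypeModel
    fused: FusedNetwork
    k: int
    assignment: ClusterAssignment
    consensus: ConsensusMatrix
    silhouette: SilhouetteProfile
    seed: int = 0
    _contribution: dict[str, float] | None = field(default=None, repr=False)

    @property
    def labels(self) -> pd.Series:
        return self.assignment.to_series()

    def modality_contribution(self, seed: int | None = None) -> dict[str, float]:
        """NMI of each single-modality clustering against the fused labels."""
        if self._contribution is None or seed is not None:
            self._contribution = _cluster.modality_contribution(
                self.model.dataset,
                self.assignment,
                self.model.snf_params,
                self.model.consensus_iterations,
                self.model.subsample_ratio,
                self.seed if seed is None else seed,
            )
        return self._contribution

    def summary(self) -> str:
        sizes = self.assignment.sizes()
        n = self.assignment.labels.size
        lines = [
            "Multi-omics subtype model (SNF + consensus spectral clustering)",
            "=" * 63,
            f"subjects: {n}    modalities: {', '.join(self.model.dataset.modalities)}",
            f"SNF: K_nn={self.model.snf_params.K_nn}, mu={self.model.snf_params.mu}, "
            f"T={self.model.snf_params.T}",
            f"consensus: {self.consensus.iterations} iterations, "
            f"ratio {self.consensus.subsample_ratio}",
            f"selected k: {self.k}",
            "subtype sizes: "
            + ", ".join(f"{lab}: {cnt} ({100 * cnt / n:.1f}%)" for lab, cnt in sorted(sizes.items())),
        ]
        if not all(np.isnan(list(self.silhouette.scores.values()))):
            lines.append("mean silhouette by k: " + ", ".join(
                f"{k}: {s:.3f}" for k, s in sorted(self.silhouette.scores.items())
            ))
        if self._contribution is not None:
            lines.append("modality contribution (NMI vs fused): " + ", ".join(
                f"{m}: {v:.3f}" for m, v in self._contribution.items()
            ))
        return "\n".join(lines)

    def plot_silhouette(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.silhouette.to_series().sort_index()
        ax.plot(s.index, s.values, marker="o")
        ax.axvline(self.k, color="grey", ls="--", lw=1)
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("mean silhouette")
        return ax

    def plot_consensus(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(self.assignment.labels, kind="stable")
        ax.imshow(self.consensus.proportion[np.ix_(order, order)], cmap="viridis",
                  vmin=0, vmax=1, interpolation="nearest")
        ax.set_title(f"consensus matrix (k={self.k})")
        return ax
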