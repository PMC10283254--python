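"""Reading, aligning, filtering and standardizing omics blocks.

An :class:`OmicsBlock` is one modality's subjects x features numeric matrix
(plasma proteins, plasma miRNAs, or whole-blood total RNA, "toRNA").  The
pipeline consumes already-normalized matrices; this module only aligns
subjects across blocks, applies a variance filter, and z-scores features so
that Euclidean distances are comparable across features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import logger

MODALITIES = ("protein", "mirna", "torna")


@dataclass
class OmicsBlock:
    """One modality's subjects x features matrix with identifiers.

    Parameters
    ----------
    modality : str
        Modality name, conventionally one of ``protein``, ``mirna``, ``torna``.
    subject_ids, feature_ids : list of str
        Ordered, unique identifiers for rows and columns.
    values : ndarray of shape (n_subjects, n_features)
        Finite numeric matrix.
    scale : str
        Free-text provenance tag describing the analysis scale.
    """

    modality: str
    subject_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    scale: str = ""

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup_s = _duplicates(self.subject_ids)
        if dup_s:
            raise ValueError(f"duplicate subject IDs: {sorted(dup_s)}")
        dup_f = _duplicates(self.feature_ids)
        if dup_f:
            raise ValueError(f"duplicate feature IDs: {sorted(dup_f)}")
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.modality} block")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str, scale: str = "") -> "OmicsBlock":
        return cls(modality, list(df.index), list(df.columns), df.to_numpy(float), scale)

    def subset_subjects(self, subject_ids: list[str]) -> "OmicsBlock":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in subject_ids]
        return replace(self, subject_ids=list(subject_ids), values=self.values[idx])


@dataclass
class MultiOmicsDataset:
    """A set of blocks sharing one subject list in identical order."""

    blocks: dict[str, OmicsBlock]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids and self.blocks:
            self.subject_ids = list(next(iter(self.blocks.values())).subject_ids)
        for name, block in self.blocks.items():
            if block.subject_ids != self.subject_ids:
                raise ValueError(f"block {name!r} subject order differs from dataset order")

    @property
    def modalities(self) -> list[str]:
        return list(self.blocks)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def read_omics_matrix(path, modality: str, delimiter: str = "\t", scale: str = "") -> OmicsBlock:
    """Read a delimited subjects x features matrix.

    The header row holds feature IDs; the first column holds subject IDs.
    Non-numeric cells, ragged rows and duplicate identifiers are errors.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject IDs in {path}: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"missing or non-finite values in {path}")
    block = OmicsBlock(modality, list(df.index.astype(str)), list(df.columns.astype(str)), values, scale)
    logger.info("read %s: %d subjects x %d features", path, block.n_subjects, block.n_features)
    return block


def write_omics_matrix(block: OmicsBlock, path, delimiter: str = "\t") -> None:
    block.to_frame().to_csv(path, sep=delimiter)


def align_subjects(blocks: list[OmicsBlock]) -> MultiOmicsDataset:
    """Restrict all blocks to the common subjects, in sorted order.

    Subjects absent from any block are dropped (and reported); an empty
    intersection is an error.
    """
    if len(blocks) < 2:
        raise ValueError("align_subjects requires at least two blocks")
    common = set(blocks[0].subject_ids)
    for b in blocks[1:]:
        common &= set(b.subject_ids)
    if not common:
        raise ValueError("no subject is present in every block")
    order = sorted(common)
    for b in blocks:
        dropped = [s for s in b.subject_ids if s not in common]
        if dropped:
            logger.info("align_subjects: dropping %d subjects from %s", len(dropped), b.modality)
    return MultiOmicsDataset({b.modality: b.subset_subjects(order) for b in blocks}, order)


def variance_filter(block: OmicsBlock, top_fraction: float) -> OmicsBlock:
    """Keep the ceil(q * F) features with largest sample variance.

    Ties are broken by lexicographic feature ID; the original feature order
    is preserved among survivors.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if block.n_features == 0:
        raise ValueError("empty block")
    if top_fraction == 1.0:
        return block
    variances = block.values.var(axis=0, ddof=1)
    n_keep = math.ceil(top_fraction * block.n_features)
    ranked = sorted(range(block.n_features), key=lambda j: (-variances[j], block.feature_ids[j]))
    keep = set(ranked[:n_keep])
    idx = [j for j in range(block.n_features) if j in keep]
    return replace(
        block,
        feature_ids=[block.feature_ids[j] for j in idx],
        values=block.values[:, idx],
    )


def standardize_features(block: OmicsBlock) -> OmicsBlock:
    """Z-score each feature column (mean 0, sample SD 1).

    Constant columns carry no distance information and are dropped with a
    log line; a block left with zero usable features is an error.
    Idempotent to numerical precision.
    """
    sd = block.values.std(axis=0, ddof=1)
    # constant columns can carry O(1e-16) rounding noise
    tol = 1e-12 * np.maximum(1.0, np.abs(block.values.mean(axis=0)))
    usable = sd > tol
    n_dropped = int((~usable).sum())
    if n_dropped:
        dropped = [f for f, u in zip(block.feature_ids, usable) if not u]
        logger.info("standardize_features(%s): dropping %d constant features: %s%s",
                    block.modality, n_dropped, dropped[:5], "..." if n_dropped > 5 else "")
    if not usable.any():
        raise ValueError(f"{block.modality}: no feature with nonzero variance")
    vals = block.values[:, usable]
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    return replace(
        block,
        feature_ids=[f for f, u in zip(block.feature_ids, usable) if u],
        values=vals,
    )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup
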