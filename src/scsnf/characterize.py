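"""Differential expression, miRNA-target expansion and pathway ORA.

Per-feature differential expression between the two subtypes uses ordinary
least squares of the feature on a subtype-1 indicator (plus optional
covariates), a two-sided t-test on the subtype coefficient, and
Benjamini-Hochberg FDR control within each modality.  Significant miRNAs
are expanded to their validated target genes (up and down separately),
and gene sets are tested for over-representation with the right-tail
hypergeometric test, BH-adjusted across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import logger


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    Pathways are clipped to the universe (violations logged); by default
    the universe is the union of all pathway genes.
    """

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        clipped = {}
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty pathway {name!r}")
            outside = genes - self.universe
            if outside:
                logger.info("pathway %s: clipping %d genes outside universe", name, len(outside))
            kept = genes & self.universe
            if kept:
                clipped[name] = kept
        self.sets = clipped


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return GeneSetCollection(sets)


def read_mirna_targets(path) -> dict[str, set[str]]:
    """Two-column TSV (mirna_id, gene_symbol) -> miRNA -> target set."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("target map needs two columns: mirna_id, gene_symbol")
    m, g = df.columns[:2]
    out: dict[str, set[str]] = {}
    for mid, sub in df.groupby(m):
        targets = set(sub[g].dropna().astype(str))
        if targets:
            out[str(mid)] = targets
    return out


def differential_expression(
    block,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """OLS differential expression of every feature on subtype.

    The estimate is subtype 1 minus subtype 2 on the analysis scale;
    direction "up"/"down" is assigned only to features with q below the
    FDR threshold.  Zero-variance features are skipped with a log line.
    """
    Y = block.to_frame()
    labels = labels.reindex(Y.index)
    if labels.isna().any():
        raise ValueError("labels missing for some subjects")
    if (labels.value_counts() < 3).any():
        raise ValueError("need >= 3 subjects per subtype")
    sd = Y.std(ddof=1)
    skipped = sd.index[sd == 0].tolist()
    if skipped:
        logger.info("differential_expression(%s): skipping %d constant features",
                    block.modality, len(skipped))
        Y = Y.drop(columns=skipped)
    X = np.column_stack([np.ones(len(Y)), (labels.to_numpy() == 1).astype(float)])
    names = ["intercept", "subtype1"]
    if covariates is not None:
        cov = covariates.reindex(Y.index).astype(float)
        if cov.isna().any().any():
            raise ValueError("missing covariate values")
        X = np.column_stack([X, cov.to_numpy()])
        names += list(cov.columns)
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    beta = H @ Y.to_numpy()  # p x F
    resid = Y.to_numpy() - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[1] / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "feature": Y.columns,
            "modality": block.modality,
            "estimate": beta[1],
            "p": pvals,
            "q": qvals,
        }
    )
    out["direction"] = np.where(
        out["q"] < fdr_threshold, np.where(out["estimate"] > 0, "up", "down"), ""
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def map_mirna_targets(
    de: pd.DataFrame, target_map: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Union target genes of significant up- and down-regulated miRNAs."""
    if not target_map:
        raise ValueError("empty miRNA target map")
    out = {"up": set(), "down": set()}
    missing = 0
    for _, row in de[de["direction"].isin(["up", "down"])].iterrows():
        targets = target_map.get(row["feature"])
        if targets is None:
            missing += 1
            continue
        out[row["direction"]] |= targets
    if missing:
        logger.info("map_mirna_targets: %d significant miRNAs absent from map", missing)
    return out


def ora_hypergeometric(
    query: set[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
    direction: str = "",
) -> pd.DataFrame:
    """Right-tail hypergeometric over-representation of each pathway.

    For pathway of size K in a universe of size N with query size m and
    overlap k: p = P(X >= k), X ~ Hypergeometric(N, K, m).  BH across the
    collection; enriched = q < threshold.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    outside = query - collection.universe
    if outside:
        logger.warning("ora: dropping %d query genes outside universe", len(outside))
    q = query & collection.universe
    if not q:
        return pd.DataFrame(
            columns=["pathway", "overlap", "pathway_size", "query_size",
                     "universe_size", "p", "q", "enriched", "direction"]
        )
    N, m = len(collection.universe), len(q)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(q & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        rows.append({"pathway": name, "overlap": k, "pathway_size": K,
                     "query_size": m, "universe_size": N, "p": p})
    out = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = qvals
    out["enriched"] = out["q"] < fdr_threshold
    out["direction"] = direction
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def enrichment_overlap(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """All Venn-partition regions of >= 2 named pathway sets.

    Each region is the set of names in exactly that combination of input
    sets; rows carry the region label, count, and sorted member listing.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least two named sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[c] for c in combo))
            outside = set().union(*(named_sets[c] for c in names if c not in combo)) \
                if len(combo) < len(names) else set()
            region = inside - outside
            rows.append({
                "region": " & ".join(combo),
                "n_sets": r,
                "count": len(region),
                "members": ";".join(sorted(region)),
            })
    return pd.DataFrame(rows)
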