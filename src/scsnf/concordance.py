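"""Agreement between molecular subtypes and an external binary risk grouping.

The external grouping (e.g. a published transcriptomic mortality-risk
signature scored elsewhere) is consumed as precomputed high/low labels.
Agreement with the subtypes is measured by Cohen's kappa with an
asymptotic 95% CI, and the risk groups are characterized by the same
KM/Cox machinery as the subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CoxResult, cox_fit, km_logrank


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    observed_agreement: float
    expected_agreement: float
    table: np.ndarray
    kappa_best_orientation: float


def cohens_kappa(a: pd.Series, b: pd.Series) -> KappaResult:
    """Cohen's kappa between two binary labelings of the same subjects.

    CI is kappa +/- 1.96 * SE with the Fleiss-Cohen-Everitt asymptotic
    variance.  Because the pairing of unrelated label alphabets is
    arbitrary, the kappa of the orientation maximizing observed agreement
    is reported alongside the raw value for the given pairing.
    """
    a, b = a.align(b, join="inner")
    if len(a) == 0:
        raise ValueError("no common subjects")
    if a.isna().any() or b.isna().any():
        raise ValueError("missing labels")
    ua, ub = sorted(a.unique()), sorted(b.unique())
    if len(ua) != 2 or len(ub) != 2:
        raise ValueError(
            f"kappa undefined: labelings must both have two levels, got {ua} and {ub}"
        )
    tab = pd.crosstab(a, b).reindex(index=ua, columns=ub, fill_value=0).to_numpy(float)
    kappa, lo, hi, po, pe = _kappa_ci(tab)
    flipped, *_ = _kappa_stats(tab[:, ::-1])
    po_f = np.trace(tab[:, ::-1]) / tab.sum()
    best = kappa if po >= po_f else flipped
    return KappaResult(kappa, lo, hi, po, pe, tab, best)


def _kappa_stats(tab: np.ndarray) -> tuple[float, float, float]:
    n = tab.sum()
    p = tab / n
    po = float(np.trace(p))
    pe = float(p.sum(1) @ p.sum(0))
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else float("nan")
    return kappa, po, pe


def _kappa_ci(tab: np.ndarray) -> tuple[float, float, float, float, float]:
    n = tab.sum()
    p = tab / n
    kappa, po, pe = _kappa_stats(tab)
    prow, pcol = p.sum(1), p.sum(0)
    # Fleiss, Cohen & Everitt (1969) large-sample variance of kappa-hat
    a = sum(
        p[i, i] * (1.0 - (prow[i] + pcol[i]) * (1.0 - kappa)) ** 2
        for i in range(p.shape[0])
    )
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (pcol[i] + prow[j]) ** 2
        for i in range(p.shape[0])
        for j in range(p.shape[1])
        if i != j
    )
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return kappa, kappa - 1.96 * se, kappa + 1.96 * se, po, pe


def risk_group_survival(
    outcomes_by_endpoint: dict[str, pd.DataFrame],
    risk: pd.Series,
    clinical: pd.DataFrame,
    antifibrotic_binary: bool = False,
) -> dict[str, dict[str, CoxResult]]:
    """Unadjusted and CPI+antifibrotic-adjusted Cox models of high vs low risk.

    Returns {endpoint: {"unadjusted": ..., "adjusted": ...}} for the
    high-risk indicator term, plus log-rank p under key "logrank_p".
    """
    levels = sorted(risk.dropna().unique())
    if len(levels) < 2:
        raise ValueError("risk grouping has a single level")
    out: dict[str, dict] = {}
    for endpoint, outcomes in outcomes_by_endpoint.items():
        risk_al = risk.reindex(outcomes.index)
        design_u = pd.DataFrame({"high_risk": (risk_al == "high").astype(float)})
        design_a = design_u.copy()
        clin = clinical.reindex(outcomes.index)
        design_a["cpi"] = clin["cpi"].astype(float)
        af = clin["antifibrotic"]
        if antifibrotic_binary:
            design_a["antifibrotic_any"] = (af != "neither").astype(float)
        else:
            design_a["antifibrotic_nintedanib"] = (af == "nintedanib").astype(float)
            design_a["antifibrotic_pirfenidone"] = (af == "pirfenidone").astype(float)
        _, logrank_p = km_logrank(outcomes, risk_al)
        out[endpoint] = {
            "unadjusted": cox_fit(outcomes, design_u, term="high_risk")[0],
            "adjusted": cox_fit(outcomes, design_a, term="high_risk")[0],
            "logrank_p": logrank_p,
        }
    return out


def median_split_risk(scores: pd.Series, source: str = "user-score") -> pd.Series:
    """Plug-in for user-supplied signature scores: high = above median."""
    high = scores > scores.median()
    return pd.Series(np.where(high, "high", "low"), index=scores.index, name=source)
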