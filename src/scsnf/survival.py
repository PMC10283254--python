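"""Composite survival endpoints, KM/Cox models, and the baseline table.

Two composite endpoints are derived per subject from dated records:

* transplant-free survival — event = lung transplant or death;
* progression-free survival — event = first >= 10 percentage-point
  absolute decline in FVC % predicted, lung transplant, or death
  (earliest wins).

Subjects with no event are censored at their last follow-up visit.  Times
are reported in months (days / 30.4375).  Hazard ratios come from Cox
proportional-hazards partial likelihood (Efron ties, Wald CIs), unadjusted
or adjusted for baseline severity (CPI) and antifibrotic treatment status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._utils import logger

DAYS_PER_MONTH = 30.4375

ENDPOINTS = ("transplant_free", "progression_free")


def compute_cpi(fvc_pct, dlco_pct, fev1_pct):
    """Composite physiologic index from lung-function % predicted values.

    CPI = 91.0 - 0.65 * DLco% - 0.53 * FVC% + 0.34 * FEV1%.  Higher is
    more severe.  Missing inputs propagate to a missing CPI.
    """
    fvc = np.asarray(fvc_pct, dtype=float)
    dlco = np.asarray(dlco_pct, dtype=float)
    fev1 = np.asarray(fev1_pct, dtype=float)
    cpi = 91.0 - 0.65 * dlco - 0.53 * fvc + 0.34 * fev1
    if cpi.ndim == 0:
        return float(cpi)
    return cpi


@dataclass
class SurvivalOutcome:
    """One subject's time-to-event record for one composite endpoint."""

    subject: str
    endpoint: str
    time_months: float
    event: bool
    event_type: str  # fvc_decline | transplant | death | censored

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError(f"negative event time for {self.subject}")
        if self.endpoint == "transplant_free" and self.event_type == "fvc_decline":
            raise ValueError("fvc_decline is not a transplant-free event")


@dataclass
class CoxResult:
    """One model term's hazard ratio with Wald CI."""

    term: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: list[str]
    n_events: int

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def _months_between(later, earlier) -> float:
    return (pd.Timestamp(later) - pd.Timestamp(earlier)).days / DAYS_PER_MONTH


def derive_transplant_free_outcome(
    subject: str,
    enrollment_date,
    transplant_date=None,
    death_date=None,
    last_followup_date=None,
) -> SurvivalOutcome:
    """Earliest of transplant and death; otherwise censored at last follow-up."""
    candidates = []
    if transplant_date is not None and not pd.isna(transplant_date):
        candidates.append((_months_between(transplant_date, enrollment_date), "transplant"))
    if death_date is not None and not pd.isna(death_date):
        candidates.append((_months_between(death_date, enrollment_date), "death"))
    if candidates:
        t, kind = min(candidates)
        if t < 0:
            raise ValueError(f"{subject}: event dated before enrollment")
        return SurvivalOutcome(subject, "transplant_free", t, True, kind)
    if last_followup_date is None or pd.isna(last_followup_date):
        raise ValueError(f"{subject}: no event and no last follow-up date")
    t = _months_between(last_followup_date, enrollment_date)
    if t < 0:
        raise ValueError(f"{subject}: follow-up dated before enrollment")
    return SurvivalOutcome(subject, "transplant_free", t, False, "censored")


def derive_progression_outcome(
    subject: str,
    enrollment_date,
    enrollment_fvc: float,
    fvc_series: pd.DataFrame,
    transplant_date=None,
    death_date=None,
    last_followup_date=None,
) -> SurvivalOutcome:
    """Earliest of first >= 10-point absolute FVC decline, transplant, death.

    The decline rule is absolute: a visit qualifies when
    ``enrollment_fvc - visit_fvc >= 10`` percentage points.
    """
    candidates = []
    last_visit_m = None
    if fvc_series is not None and len(fvc_series):
        for _, row in fvc_series.sort_values("visit_date").iterrows():
            t = _months_between(row["visit_date"], enrollment_date)
            if t < 0:
                raise ValueError(f"{subject}: visit dated before enrollment")
            last_visit_m = t
            if enrollment_fvc - float(row["fvc_pct"]) >= 10.0:
                candidates.append((t, "fvc_decline"))
                break
    if transplant_date is not None and not pd.isna(transplant_date):
        candidates.append((_months_between(transplant_date, enrollment_date), "transplant"))
    if death_date is not None and not pd.isna(death_date):
        candidates.append((_months_between(death_date, enrollment_date), "death"))
    if candidates:
        t, kind = min(candidates)
        if t < 0:
            raise ValueError(f"{subject}: event dated before enrollment")
        return SurvivalOutcome(subject, "progression_free", t, True, kind)
    if last_followup_date is not None and not pd.isna(last_followup_date):
        t = _months_between(last_followup_date, enrollment_date)
    elif last_visit_m is not None:
        t = last_visit_m
    else:
        raise ValueError(f"{subject}: no event and no follow-up information")
    return SurvivalOutcome(subject, "progression_free", t, False, "censored")


def derive_outcomes(
    clinical: pd.DataFrame, fvc_long: pd.DataFrame, events: pd.DataFrame, endpoint: str
) -> pd.DataFrame:
    """Vector version over a cohort; returns subject-indexed time/event table."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    by_subject = dict(tuple(fvc_long.groupby("subject"))) if len(fvc_long) else {}
    rows = []
    for subject, crow in clinical.iterrows():
        erow = events.loc[subject] if subject in events.index else pd.Series(dtype=object)
        kwargs = dict(
            transplant_date=erow.get("transplant_date"),
            death_date=erow.get("death_date"),
            last_followup_date=erow.get("last_followup_date"),
        )
        if endpoint == "transplant_free":
            out = derive_transplant_free_outcome(subject, crow["enrollment_date"], **kwargs)
        else:
            out = derive_progression_outcome(
                subject,
                crow["enrollment_date"],
                float(crow["fvc_pct"]),
                by_subject.get(subject),
                **kwargs,
            )
        rows.append((subject, out.time_months, int(out.event), out.event_type))
    return pd.DataFrame(
        rows, columns=["subject", "time_months", "event", "event_type"]
    ).set_index("subject")


def km_logrank(outcomes: pd.DataFrame, groups: pd.Series):
    """Kaplan-Meier fits per group plus the log-rank test p-value."""
    groups = groups.reindex(outcomes.index)
    if groups.isna().any():
        raise ValueError("groups missing for some subjects")
    fits = {}
    for g, sub in outcomes.groupby(groups):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no subjects")
        km = KaplanMeierFitter(label=str(g))
        km.fit(sub["time_months"], sub["event"])
        fits[g] = km
    if outcomes["event"].sum() == 0:
        p = 1.0
    else:
        p = float(
            multivariate_logrank_test(
                outcomes["time_months"], groups, outcomes["event"]
            ).p_value
        )
    return fits, p


def cox_fit(
    outcomes: pd.DataFrame,
    design: pd.DataFrame,
    term: str | None = None,
) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CIs).

    ``design`` holds numeric covariate columns indexed by subject; every
    column enters the model.  Returns one CoxResult per column (or just
    ``term`` if given).
    """
    df = design.join(outcomes[["time_months", "event"]], how="inner").dropna()
    if df["event"].sum() == 0:
        raise ValueError("no events in the analysis set")
    constant = [c for c in design.columns if df[c].nunique() <= 1 and c != term]
    if constant:
        logger.info("cox_fit: dropping constant covariates %s", constant)
        df = df.drop(columns=constant)
    last_err: Exception | None = None
    for penalizer in (0.0, 0.1, 1.0):
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            cph.fit(df, duration_col="time_months", event_col="event")
            break
        except (ConvergenceError, ValueError) as exc:
            # tiny cohorts can separate completely; a light ridge restores
            # a finite maximum without materially shrinking well-posed fits
            last_err = exc
            logger.warning("cox_fit: no convergence at penalizer=%s; retrying", penalizer)
    else:
        raise last_err
    results = []
    summ = cph.summary
    for name, row in summ.iterrows():
        results.append(
            CoxResult(
                term=str(name),
                hazard_ratio=float(np.exp(row["coef"])),
                ci_low=float(np.exp(row["coef lower 95%"])),
                ci_high=float(np.exp(row["coef upper 95%"])),
                p_value=float(row["p"]),
                covariates=[c for c in design.columns],
                n_events=int(df["event"].sum()),
            )
        )
    if term is not None:
        results = [r for r in results if r.term == term]
        if not results:
            raise ValueError(f"term {term!r} not in fitted model")
    return results


def subtype_design(
    labels: pd.Series,
    clinical: pd.DataFrame | None = None,
    adjusted: bool = False,
    antifibrotic_binary: bool = False,
) -> pd.DataFrame:
    """Design matrix: subtype-1 indicator, optionally CPI + antifibrotic.

    The antifibrotic covariate is a 3-level category (reference
    "neither") unless ``antifibrotic_binary``.
    """
    design = pd.DataFrame({"subtype1": (labels == 1).astype(float)})
    if adjusted:
        if clinical is None:
            raise ValueError("adjusted design requires the clinical table")
        design["cpi"] = clinical.reindex(labels.index)["cpi"].astype(float)
        af = clinical.reindex(labels.index)["antifibrotic"]
        if antifibrotic_binary:
            design["antifibrotic_any"] = (af != "neither").astype(float)
        else:
            design["antifibrotic_nintedanib"] = (af == "nintedanib").astype(float)
            design["antifibrotic_pirfenidone"] = (af == "pirfenidone").astype(float)
        n_missing = int(design.isna().any(axis=1).sum())
        if n_missing:
            logger.info("cox: excluding %d subjects with missing covariates", n_missing)
    return design


CONTINUOUS_VARS = ["age", "fvc_pct", "dlco_pct", "fev1_pct", "cpi"]
CATEGORICAL_VARS = [
    "sex", "ever_smoker", "cad", "copd", "diabetes",
    "antifibrotic", "gap_stage", "diagnostic_category",
]


def categorical_p(table: np.ndarray) -> float:
    """Chi-square p for a levels x groups count table.

    Yates continuity correction applies to 2x2 tables only, plain Pearson
    chi-square otherwise (scipy's default convention).
    """
    res = stats.chi2_contingency(np.asarray(table))
    return float(res.pvalue)


def baseline_table(
    clinical: pd.DataFrame,
    labels: pd.Series,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Baseline characteristics by subtype with group-difference tests.

    Continuous variables: mean (SD) per group, Kruskal-Wallis p.
    Categorical variables: count (%) per group, chi-square p.  Missing
    rows are dropped per variable.  P-values are reported to 2 decimals.
    """
    continuous = [v for v in (continuous or CONTINUOUS_VARS) if v in clinical.columns]
    categorical = [v for v in (categorical or CATEGORICAL_VARS) if v in clinical.columns]
    labels = labels.reindex(clinical.index)
    group_levels = sorted(labels.dropna().unique())
    rows = []
    for var in continuous:
        x = clinical[var].astype(float)
        keep = x.notna() & labels.notna()
        samples = [x[keep & (labels == g)] for g in group_levels]
        p = float(stats.kruskal(*samples).pvalue)
        cells = {f"subtype_{g}": f"{s.mean():.2f} ({s.std(ddof=1):.2f})"
                 for g, s in zip(group_levels, samples)}
        rows.append({"variable": var, "level": "", **cells, "p": round(p, 2)})
    for var in categorical:
        x = clinical[var]
        keep = x.notna() & labels.notna()
        tab = pd.crosstab(x[keep], labels[keep])
        if tab.shape[0] < 2:
            raise ValueError(f"variable {var!r} has a single level")
        p = categorical_p(tab.to_numpy())
        for level, trow in tab.iterrows():
            cells = {}
            for g in group_levels:
                cnt = int(trow.get(g, 0))
                tot = int(tab[g].sum())
                cells[f"subtype_{g}"] = f"{cnt} ({100 * cnt / tot:.1f}%)"
            rows.append({"variable": var, "level": str(level), **cells, "p": round(p, 2)})
    return pd.DataFrame(rows)
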