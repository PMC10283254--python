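"""Cross-validated random-forest classification of molecular subtype.

A 5-fold stratified cross-validation: within each training fold a random
forest ranks all candidate features (protein + miRNA by default), the top
``screen_size`` are kept, a forest is refit on the screened set, and the
held-out fold is scored by ROC AUC of the predicted subtype-1
probability.  Features screened in at least ``selection_threshold`` of
the folds form the reported ledger, with the mean and SD of their refit
variable importances across the folds where they were selected.

Clinical consistency: per fold, the predicted labels (in-sample for the
training subjects, out-of-fold for the validation subjects) are related
to each composite endpoint by a Cox model, checking that the hazard-ratio
point estimates point the same way across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._utils import small_seed
from .survival import cox_fit


@dataclass
class ClassifierConfig:
    n_folds: int = 5
    selection_threshold: int = 3
    n_estimators: int = 500
    max_depth: int | None = None
    screen_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_threshold > self.n_folds:
            raise ValueError("selection_threshold cannot exceed n_folds")
        if self.n_estimators < 100:
            raise ValueError("forest size must be >= 100")


@dataclass
class ClassifierReport:
    fold_auc: list[float]
    selections: list[dict[str, float]]  # per fold: feature -> importance
    oof_proba: pd.Series  # out-of-fold P(subtype 1)
    fold_of: pd.Series  # validation fold per subject
    train_pred: list[pd.Series]  # per fold: in-sample predicted labels
    val_pred: list[pd.Series]  # per fold: out-of-fold predicted labels
    config: ClassifierConfig = field(default=None)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1))


def run_cv_classifier(
    X: pd.DataFrame, labels: pd.Series, config: ClassifierConfig | None = None
) -> ClassifierReport:
    """Stratified k-fold CV with within-fold feature screening.

    ``X`` is subjects x features; ``labels`` takes values 1/2.  All
    screening and fitting touch only the training fold.
    """
    config = config or ClassifierConfig()
    labels = labels.reindex(X.index)
    if labels.isna().any():
        raise ValueError("labels missing for some subjects")
    y = (labels.to_numpy() == 1).astype(int)
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError("need both subtypes present")
    if counts.min() < config.n_folds:
        raise ValueError("more folds than minority-class subjects")
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed & 0x7FFFFFFF
    )
    fold_auc: list[float] = []
    selections: list[dict[str, float]] = []
    oof = pd.Series(np.nan, index=X.index, name="p_subtype1")
    fold_of = pd.Series(-1, index=X.index, name="fold", dtype=int)
    train_pred, val_pred = [], []
    cols = np.asarray(X.columns)
    Xv = X.to_numpy(float)
    for fold, (tr, va) in enumerate(skf.split(Xv, y)):
        screen_rf = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            random_state=small_seed(config.seed, "screen", fold),
            n_jobs=1,
        ).fit(Xv[tr], y[tr])
        k = min(config.screen_size, Xv.shape[1])
        order = np.argsort(-screen_rf.feature_importances_, kind="stable")[:k]
        rf = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            random_state=small_seed(config.seed, "refit", fold),
            n_jobs=1,
        ).fit(Xv[tr][:, order], y[tr])
        selections.append(dict(zip(cols[order], rf.feature_importances_)))
        proba = rf.predict_proba(Xv[va][:, order])[:, list(rf.classes_).index(1)]
        fold_auc.append(float(roc_auc_score(y[va], proba)))
        oof.iloc[va] = proba
        fold_of.iloc[va] = fold
        tr_p = rf.predict_proba(Xv[tr][:, order])[:, list(rf.classes_).index(1)]
        train_pred.append(
            pd.Series(np.where(tr_p >= 0.5, 1, 2), index=X.index[tr], name="pred")
        )
        val_pred.append(
            pd.Series(np.where(proba >= 0.5, 1, 2), index=X.index[va], name="pred")
        )
    return ClassifierReport(fold_auc, selections, oof, fold_of, train_pred, val_pred, config)


def tally_selected_features(
    report: ClassifierReport, modality_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Ledger of features screened in >= selection_threshold folds.

    Columns: feature, modality, n_selected, mean_importance, sd_importance,
    selected_all (flag for features present in every fold).  Sorted by
    mean importance, descending.
    """
    config = report.config or ClassifierConfig()
    counts: dict[str, list[float]] = {}
    for sel in report.selections:
        for feat, imp in sel.items():
            counts.setdefault(feat, []).append(float(imp))
    rows = []
    for feat, imps in counts.items():
        if len(imps) < config.selection_threshold:
            continue
        rows.append(
            {
                "feature": feat,
                "modality": (modality_of or {}).get(feat, feat.split("_")[0]),
                "n_selected": len(imps),
                "mean_importance": float(np.mean(imps)),
                "sd_importance": float(np.std(imps, ddof=1)) if len(imps) > 1 else 0.0,
                "selected_all": len(imps) == len(report.selections),
            }
        )
    ledger = pd.DataFrame(
        rows,
        columns=["feature", "modality", "n_selected", "mean_importance",
                 "sd_importance", "selected_all"],
    )
    return ledger.sort_values(
        ["mean_importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)


def validate_clinical_consistency(
    report: ClassifierReport, outcomes_by_endpoint: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-fold Cox HR of predicted subtype in training and validation subsets.

    Folds with no events (or a single predicted class) in a subset yield an
    undefined (NaN) HR for that cell; the run continues.  The returned
    frame carries a ``direction_consistent`` attr: True when all defined
    HRs sit on the same side of 1 within each endpoint.
    """
    rows = []
    for fold in range(len(report.train_pred)):
        for subset, preds in (("training", report.train_pred[fold]),
                              ("validation", report.val_pred[fold])):
            for endpoint, outcomes in outcomes_by_endpoint.items():
                sub = outcomes.reindex(preds.index).dropna()
                hr = ci_lo = ci_hi = p = np.nan
                if sub["event"].sum() > 0 and preds.loc[sub.index].nunique() == 2:
                    design = pd.DataFrame(
                        {"pred_subtype1": (preds.loc[sub.index] == 1).astype(float)}
                    )
                    try:
                        res = cox_fit(sub, design, term="pred_subtype1")[0]
                        hr, ci_lo, ci_hi, p = (res.hazard_ratio, res.ci_low,
                                               res.ci_high, res.p_value)
                    except Exception:  # degenerate fold (e.g. complete separation)
                        pass
                rows.append({"fold": fold, "subset": subset, "endpoint": endpoint,
                             "hr": hr, "ci_low": ci_lo, "ci_high": ci_hi, "p": p})
    table = pd.DataFrame(rows)
    consistent = True
    for endpoint in outcomes_by_endpoint:
        hrs = table.loc[table["endpoint"] == endpoint, "hr"].dropna()
        if len(hrs) and not ((hrs > 1).all() or (hrs < 1).all()):
            consistent = False
    table.attrs["direction_consistent"] = consistent
    return table
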