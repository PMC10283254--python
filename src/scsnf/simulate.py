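"""Synthetic multi-omics cohort generator.

Emulates a blood multi-omics IPF cohort: three already-normalized blocks
(plasma proteins, plasma miRNAs, whole-blood total RNA) over the same
subjects, with a planted two-subtype structure whose signal lives in the
protein and miRNA blocks but not the toRNA block; plus a clinical table
(lung-function percentages, CPI, antifibrotic category), a longitudinal FVC
table on a fixed visit grid, and event dates (transplant/death/last
follow-up) drawn from exponential hazards with subtype and CPI log-hazard
effects.

The generative model is Gaussian on the post-normalization scale:
informative features of a modality have subtype-specific means separated by
``effect_size * noise_sd``; all other features share one mean.  Subtype 1
is the clinically severe group: lower baseline FVC/DLco/FEV1 (hence higher
CPI), a steeper mean annual FVC slope, and (by default) a higher hazard of
transplant/death.  All randomness flows from ``SimulationConfig.seed``
through fixed per-table derivations, so the same config reproduces the same
bytes on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import rng_for
from .io import MODALITIES, OmicsBlock, write_omics_matrix
from .survival import DAYS_PER_MONTH, compute_cpi

EPOCH = pd.Timestamp("2018-01-01")


@dataclass
class SurvivalSimConfig:
    """Event-process parameters (time unit: months).

    baseline_hazard
        Exponential hazards per month for death and transplant.
    log_hr_subtype
        Log hazard ratio of subtype-1 membership (both event types).
    log_hr_cpi
        Log hazard ratio per CPI unit above the centering value.
    cpi_center
        CPI value at which the baseline hazard applies.
    admin_censor_months
        Administrative censoring horizon; 0 is the degenerate everyone-
        censored-at-enrollment case, negative values are invalid.
    dropout_rate
        Exponential hazard of loss to follow-up per month.
    """

    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"death": 0.008, "transplant": 0.003}
    )
    log_hr_subtype: float = math.log(1.8)
    log_hr_cpi: float = 0.04
    cpi_center: float = 52.0
    admin_censor_months: float = 48.0
    dropout_rate: float = 0.004

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.baseline_hazard.values()):
            raise ValueError("baseline hazards must be nonnegative")
        if self.admin_censor_months < 0:
            raise ValueError("admin censoring time must be >= 0")
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be nonnegative")


@dataclass
class SimulationConfig:
    """Study-level simulation settings.

    The defaults are the paper-like preset: 232 subjects in a 45/55 split,
    subtype signal planted in the protein and miRNA blocks only
    (informative fraction 0 for toRNA), mean shifts of 2 within-cluster
    SDs, and subtype-1-severe clinical/survival structure.
    """

    n_subjects: int = 232
    cluster_proportions: tuple[float, ...] = (0.45, 0.55)
    n_features: dict[str, int] = field(
        default_factory=lambda: {"protein": 1300, "mirna": 750, "torna": 1600}
    )
    informative_fraction: dict[str, float] = field(
        default_factory=lambda: {"protein": 0.10, "mirna": 0.15, "torna": 0.0}
    )
    effect_size: float = 2.0
    noise_sd: float = 1.0
    # baseline lung function: subtype-2 means; subtype-1 gets `clinical_shift`
    # subtracted (Table-1-like severity gradient). SDs in percentage points.
    lung_means: dict[str, float] = field(
        default_factory=lambda: {"fvc": 73.8, "dlco": 43.1, "fev1": 81.0}
    )
    lung_sds: dict[str, float] = field(
        default_factory=lambda: {"fvc": 16.0, "dlco": 13.0, "fev1": 18.0}
    )
    clinical_shift: dict[str, float] = field(
        default_factory=lambda: {"fvc": 5.9, "dlco": 4.8, "fev1": 4.9}
    )
    # annual FVC %-predicted slope by subtype (mean), with between-subject SD
    fvc_slope_mean: dict[int, float] = field(default_factory=lambda: {1: -6.5, 2: -2.5})
    fvc_slope_sd: float = 2.0
    fvc_visit_sd: float = 2.0
    visit_interval_months: float = 4.0
    antifibrotic_probs: tuple[float, float, float] = (0.18, 0.36, 0.46)
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9 or any(
            p < 0 for p in self.cluster_proportions
        ):
            raise ValueError("cluster_proportions must be a probability vector")
        for m, f in self.n_features.items():
            if f <= 0:
                raise ValueError(f"non-positive feature count for {m}")
        for m, q in self.informative_fraction.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"informative_fraction[{m}] must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A no-signal preset: no omics shift, no clinical shift, no
        subtype hazard effect, equal FVC slopes."""
        cfg = cls(
            effect_size=0.0,
            clinical_shift={"fvc": 0.0, "dlco": 0.0, "fev1": 0.0},
            fvc_slope_mean={1: -3.0, 2: -3.0},
        )
        cfg = replace(cfg, survival=replace(cfg.survival, log_hr_subtype=0.0))
        return replace(cfg, **overrides)

    @classmethod
    def smoke(cls, **overrides) -> "SimulationConfig":
        """A tiny fast preset for end-to-end smoke runs."""
        cfg = cls(
            n_subjects=10,
            n_features={"protein": 30, "mirna": 20, "torna": 40},
        )
        return replace(cfg, **overrides)


@dataclass
class SimulatedStudy:
    """All simulated tables plus the ground-truth labels (kept separate
    from anything a pipeline stage reads as input)."""

    blocks: dict[str, OmicsBlock]
    clinical: pd.DataFrame
    fvc_long: pd.DataFrame
    events: pd.DataFrame
    risk_groups: pd.DataFrame
    true_labels: pd.Series


def _subject_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_labels(config: SimulationConfig) -> pd.Series:
    rng = rng_for(config.seed, "labels")
    k = len(config.cluster_proportions)
    labels = rng.choice(np.arange(1, k + 1), size=config.n_subjects, p=config.cluster_proportions)
    return pd.Series(labels, index=_subject_ids(config.n_subjects), name="true_subtype")


def simulate_omics_block(
    config: SimulationConfig, modality: str, labels: pd.Series
) -> OmicsBlock:
    """Draw one modality's matrix given subject labels.

    Informative features (the first ``round(frac * F)`` columns) get
    subtype-specific means at ``+/- effect_size * noise_sd / 2``; the rest
    share mean zero.  Noise is iid Gaussian with SD ``noise_sd``.
    """
    if modality not in config.n_features:
        raise ValueError(f"unknown modality {modality!r}")
    n_feat = config.n_features[modality]
    if n_feat <= 0:
        raise ValueError(f"non-positive feature count for {modality}")
    if len(labels) != config.n_subjects:
        raise ValueError("labels must cover all subjects")
    rng = rng_for(config.seed, "omics", modality)
    n = config.n_subjects
    frac = config.informative_fraction.get(modality, 0.0)
    n_inf = int(round(frac * n_feat))
    delta = config.effect_size * config.noise_sd
    means = np.zeros((n, n_feat))
    signs = np.where(labels.to_numpy() == 1, 0.5, -0.5)
    if n_inf:
        # alternate shift direction across informative features
        direction = np.where(np.arange(n_inf) % 2 == 0, 1.0, -1.0)
        means[:, :n_inf] = np.outer(signs, direction) * delta
    values = means + rng.normal(0.0, config.noise_sd, size=(n, n_feat))
    feats = [f"{modality}_f{j + 1:05d}" for j in range(n_feat)]
    return OmicsBlock(modality, list(labels.index), feats, values, scale="simulated-normalized")


def simulate_clinical_and_survival(
    config: SimulationConfig, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Clinical, longitudinal-FVC and event-date tables for given labels.

    Event times come from independent exponential clocks for death and
    transplant whose hazards multiply ``exp(log_hr_subtype)`` for subtype-1
    subjects and ``exp(log_hr_cpi * (CPI - cpi_center))``.  Longitudinal
    FVC follows subject-specific linear slopes on a fixed visit grid, so
    the first >= 10-point absolute decline happens earlier for steeper
    slopes; visits stop at the earliest of death, transplant and censoring.
    """
    if len(labels) != config.n_subjects:
        raise ValueError("labels must cover all subjects")
    sv = config.survival
    rng = rng_for(config.seed, "clinical")
    n = config.n_subjects
    lab = labels.to_numpy()
    sev = (lab == 1).astype(float)

    def lungvar(name: str) -> np.ndarray:
        x = rng.normal(config.lung_means[name], config.lung_sds[name], n)
        x = x - sev * config.clinical_shift[name]
        return np.clip(x, 20.0, 149.0)

    fvc0 = lungvar("fvc")
    dlco0 = lungvar("dlco")
    fev10 = lungvar("fev1")
    cpi = compute_cpi(fvc0, dlco0, fev10)
    age = np.clip(rng.normal(69.7, 7.8, n), 40, 95)
    sex = rng.choice(["M", "F"], size=n, p=[0.74, 0.26])
    smoker = rng.random(n) < 0.67
    cad = rng.random(n) < 0.31
    copd = rng.random(n) < 0.18
    diabetes = rng.random(n) < 0.19
    antifib = rng.choice(
        ["nintedanib", "pirfenidone", "neither"], size=n, p=config.antifibrotic_probs
    )
    gap = rng.choice([1, 2, 3], size=n, p=[0.27, 0.58, 0.15])
    diag = rng.choice(["definite", "probable", "possible"], size=n, p=[0.74, 0.22, 0.04])
    enroll_offset = rng.integers(0, 365, n)
    enroll = EPOCH + pd.to_timedelta(enroll_offset, unit="D")

    clinical = pd.DataFrame(
        {
            "subject": labels.index,
            "age": np.round(age, 1),
            "sex": sex,
            "ever_smoker": smoker.astype(int),
            "cad": cad.astype(int),
            "copd": copd.astype(int),
            "diabetes": diabetes.astype(int),
            "antifibrotic": antifib,
            "fvc_pct": np.round(fvc0, 1),
            "dlco_pct": np.round(dlco0, 1),
            "fev1_pct": np.round(fev10, 1),
            "gap_stage": gap,
            "diagnostic_category": diag,
            "enrollment_date": enroll.strftime("%Y-%m-%d"),
        }
    ).set_index("subject")
    clinical["cpi"] = np.round(
        compute_cpi(clinical["fvc_pct"], clinical["dlco_pct"], clinical["fev1_pct"]), 1
    )

    # event clocks (months)
    lp = sv.log_hr_subtype * sev + sv.log_hr_cpi * (cpi - sv.cpi_center)
    t_death = _exp_times(rng, sv.baseline_hazard.get("death", 0.0) * np.exp(lp))
    t_tx = _exp_times(rng, sv.baseline_hazard.get("transplant", 0.0) * np.exp(lp))
    t_drop = _exp_times(rng, np.full(n, sv.dropout_rate))
    censor = np.minimum(sv.admin_censor_months, t_drop)

    death_m = np.where(t_death <= censor, t_death, np.nan)
    tx_m = np.where((t_tx <= censor) & (t_tx < t_death), t_tx, np.nan)
    followup_end = np.nanmin(
        np.column_stack([censor, np.where(np.isnan(death_m), np.inf, death_m)]), axis=1
    )

    def to_date(months: np.ndarray) -> pd.Series:
        days = np.round(months * DAYS_PER_MONTH)
        out = pd.Series(pd.NaT, index=labels.index, dtype="datetime64[ns]")
        ok = np.isfinite(days)
        out[ok] = enroll[ok] + pd.to_timedelta(days[ok], unit="D")
        return out

    events = pd.DataFrame(
        {
            "subject": labels.index,
            "transplant_date": to_date(tx_m).dt.strftime("%Y-%m-%d"),
            "death_date": to_date(death_m).dt.strftime("%Y-%m-%d"),
            "last_followup_date": to_date(followup_end).dt.strftime("%Y-%m-%d"),
        }
    ).set_index("subject")

    # longitudinal FVC on the visit grid, stopped at event/censoring
    slope = rng.normal(
        np.array([config.fvc_slope_mean[int(l)] for l in lab]), config.fvc_slope_sd
    )
    visit_stop = np.nanmin(
        np.column_stack([followup_end, np.where(np.isnan(tx_m), np.inf, tx_m)]), axis=1
    )
    rows = []
    if config.visit_interval_months > 0:
        max_visits = int(np.floor(sv.admin_censor_months / config.visit_interval_months)) + 1
        for v in range(1, max_visits + 1):
            t = v * config.visit_interval_months
            active = t <= visit_stop
            if not active.any():
                break
            vals = fvc0 + slope * (t / 12.0) + rng.normal(0, config.fvc_visit_sd, n)
            dates = enroll + pd.to_timedelta(np.round(t * DAYS_PER_MONTH), unit="D")
            for i in np.flatnonzero(active):
                rows.append(
                    (labels.index[i], dates[i].strftime("%Y-%m-%d"), round(max(vals[i], 10.0), 1))
                )
    fvc_long = pd.DataFrame(rows, columns=["subject", "visit_date", "fvc_pct"])
    return clinical, fvc_long, events


def _exp_times(rng: np.random.Generator, hazard: np.ndarray) -> np.ndarray:
    """Exponential event times; zero hazard means the event never occurs."""
    u = rng.random(len(hazard))
    with np.errstate(divide="ignore"):
        return np.where(hazard > 0, -np.log(u) / np.where(hazard > 0, hazard, 1.0), np.inf)


def simulate_risk_groups(config: SimulationConfig, clinical: pd.DataFrame) -> pd.DataFrame:
    """A severity-driven binary risk grouping (external-signature analogue).

    High risk = noisy CPI above the cohort median, so the grouping tracks
    transplant-free survival but is only weakly tied to the planted
    molecular subtypes.
    """
    rng = rng_for(config.seed, "risk")
    score = clinical["cpi"].to_numpy() + rng.normal(0, 8.0, len(clinical))
    high = score > np.median(score)
    return pd.DataFrame(
        {"subject": clinical.index, "risk_group": np.where(high, "high", "low")}
    ).set_index("subject")


def simulate_study(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedStudy:
    """Compose labels, omics blocks, clinical/survival tables; optionally
    write every table in the pipeline's input formats."""
    labels = simulate_labels(config)
    blocks = {m: simulate_omics_block(config, m, labels) for m in config.n_features}
    clinical, fvc_long, events = simulate_clinical_and_survival(config, labels)
    risk = simulate_risk_groups(config, clinical)
    study = SimulatedStudy(blocks, clinical, fvc_long, events, risk, labels)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for m, block in blocks.items():
            write_omics_matrix(block, outdir / f"{m}.tsv")
        clinical.to_csv(outdir / "clinical.tsv", sep="\t")
        fvc_long.to_csv(outdir / "fvc_long.tsv", sep="\t", index=False)
        events.to_csv(outdir / "events.tsv", sep="\t")
        risk.to_csv(outdir / "risk_groups.tsv", sep="\t")
        labels.to_frame().to_csv(outdir / "truth.tsv", sep="\t")
        _write_gene_resources(config, outdir)
    return study


def _write_gene_resources(config: SimulationConfig, outdir: Path) -> None:
    """Synthetic gene-set (GMT) and miRNA-target resources keyed to the
    simulated feature IDs, so the enrichment stage runs self-contained."""
    rng = rng_for(config.seed, "genesets")
    n_genes = 400
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    n_mirna = config.n_features.get("mirna", 0)
    mirnas = [f"mirna_f{j + 1:05d}" for j in range(n_mirna)]
    with open(outdir / "mirna_targets.tsv", "w") as fh:
        fh.write("mirna_id\tgene_symbol\n")
        for m in mirnas:
            targets = rng.choice(genes, size=rng.integers(3, 12), replace=False)
            for g in sorted(targets):
                fh.write(f"{m}\t{g}\n")
    with open(outdir / "gene_sets.gmt", "w") as fh:
        for p in range(40):
            members = rng.choice(genes, size=rng.integers(10, 40), replace=False)
            fh.write("\t".join([f"PATHWAY_{p + 1:02d}", "synthetic"] + sorted(members)) + "\n")
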