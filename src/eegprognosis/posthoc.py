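"""Post-hoc analyses: subgroup AUCs, per-marker comparison, survival.

These run on the prediction sets produced by the evaluation module:
recomputing AUC within clinical strata, repeating the nested CV per marker
on identical splits, dichotomizing predicted risk, and relating it to the
censored time-to-recurrence outcome with Cox and Kaplan-Meier models.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.proportion import proportion_confint

from .config import ModelSpec
from .evaluation import (
    EvaluationResult,
    FeatureMatrix,
    PredictionSet,
    auc_ci_ledell,
    nested_cv_evaluate,
)

logger = logging.getLogger(__name__)

#: Minimum EEGs per class inside a stratum before its AUC is estimated.
MIN_STRATUM_CLASS_SIZE = 5

SUBGROUP_VARIABLES = (
    "age_group", "sex", "focal_lesion", "ied_status", "slowing",
    "asm_count", "epilepsy_type",
)


# ---------------------------------------------------------------------------
# Subgroup AUCs
# ---------------------------------------------------------------------------


@dataclass
class SubgroupSpec:
    """A cohort partition: one clinical variable and its strata."""

    variable: str

    def __post_init__(self) -> None:
        if self.variable not in SUBGROUP_VARIABLES:
            raise ValueError(
                f"unknown subgroup variable {self.variable!r}; "
                f"expected one of {SUBGROUP_VARIABLES}"
            )

    def strata(self, cohort: pd.DataFrame) -> pd.Series:
        """Stratum label per EEG (indexed by eeg_id)."""
        c = cohort.set_index("eeg_id")
        if self.variable == "age_group":
            vals = pd.cut(
                c["age"],
                bins=[-np.inf, 40.0, 60.0, np.inf],
                labels=["18-40", "40-60", ">60"],
            ).astype(str)
        elif self.variable == "asm_count":
            vals = pd.cut(
                c["asm_count"],
                bins=[-np.inf, 0, 1, np.inf],
                labels=["0", "1", ">=2"],
            ).astype(str)
        else:
            vals = c[self.variable].astype(str)
        return vals


def subgroup_auc(
    predictions: PredictionSet,
    cohort: pd.DataFrame,
    spec: SubgroupSpec,
) -> pd.DataFrame:
    """Per-stratum cross-validated AUC using the existing fold assignment.

    Strata with fewer than ``MIN_STRATUM_CLASS_SIZE`` EEGs in either class
    are reported as not estimable instead of raising.
    """
    strata = spec.strata(cohort)
    per_eeg = predictions.per_eeg.copy()
    per_eeg["stratum"] = strata.reindex(per_eeg["eeg_id"]).to_numpy()
    rows = []
    for stratum, sub in per_eeg.groupby("stratum", sort=True):
        y = sub["label"].to_numpy().astype(bool)
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        estimable = min(n_pos, n_neg) >= MIN_STRATUM_CLASS_SIZE
        if estimable:
            res = auc_ci_ledell(
                sub["score"].to_numpy(), y, sub["fold"].to_numpy()
            )
            rows.append(
                dict(variable=spec.variable, stratum=stratum, n_eegs=len(sub),
                     n_pos=n_pos, auc=res.auc, ci_low=res.ci_low,
                     ci_high=res.ci_high, p_vs_chance=res.p_vs_chance,
                     estimable=True)
            )
        else:
            rows.append(
                dict(variable=spec.variable, stratum=stratum, n_eegs=len(sub),
                     n_pos=n_pos, auc=np.nan, ci_low=np.nan, ci_high=np.nan,
                     p_vs_chance=np.nan, estimable=False)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-marker comparison
# ---------------------------------------------------------------------------


def fold_manifest_hash(patient_ids: np.ndarray, fold_ids: np.ndarray) -> str:
    pairs = sorted(zip(map(str, patient_ids), map(int, fold_ids)))
    return hashlib.sha1(repr(pairs).encode()).hexdigest()[:12]


def compare_markers(
    features_by_marker: dict[str, FeatureMatrix],
    model_spec: Optional[ModelSpec] = None,
    fold_ids: Optional[np.ndarray] = None,
    inner_k: int = 10,
    outer_k: int = 5,
    q: float = 0.5,
    seed: int = 0,
    include_union: bool = True,
) -> pd.DataFrame:
    """Nested CV repeated per marker subset on identical CV splits.

    ``features_by_marker`` maps marker names to per-marker feature matrices
    over the same epochs (plus, when ``include_union``, a ``combined``
    entry is evaluated over the union of columns). The shared outer-fold
    assignment is hashed into the result table so identical splits are
    auditable. Markers whose features are entirely missing are skipped.
    """
    from .evaluation import _outer_folds_with_both_classes

    names = list(features_by_marker)
    first = features_by_marker[names[0]]
    if fold_ids is None:
        fold_ids = _outer_folds_with_both_classes(first, outer_k, seed)
    manifest = fold_manifest_hash(first.patient_ids, fold_ids)
    rows = []
    union_frames = []
    for name in names:
        fm = features_by_marker[name]
        if fm.X.isna().all().all():
            logger.warning("compare_markers: marker %s all-missing; skipped", name)
            continue
        res, _ = nested_cv_evaluate(
            fm, model_spec, inner_k=inner_k, q=q, seed=seed, fold_ids=fold_ids
        )
        logger.info("compare_markers: marker=%s folds=%s auc=%.3f", name, manifest, res.auc)
        rows.append(dict(marker=name, auc=res.auc, ci_low=res.ci_low,
                         ci_high=res.ci_high, p_vs_chance=res.p_vs_chance,
                         fold_manifest=manifest))
        union_frames.append(fm.X)
    if include_union and len(union_frames) > 1:
        union = FeatureMatrix(
            X=pd.concat(union_frames, axis=1),
            eeg_ids=first.eeg_ids,
            patient_ids=first.patient_ids,
            labels=first.labels,
            age=first.age,
        )
        res, _ = nested_cv_evaluate(
            union, model_spec, inner_k=inner_k, q=q, seed=seed, fold_ids=fold_ids
        )
        rows.append(dict(marker="combined", auc=res.auc, ci_low=res.ci_low,
                         ci_high=res.ci_high, p_vs_chance=res.p_vs_chance,
                         fold_manifest=manifest))
    return (
        pd.DataFrame(rows)
        .sort_values("auc", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Risk dichotomization and survival
# ---------------------------------------------------------------------------


def dichotomize_risk(per_eeg_scores: np.ndarray, method: str = "mean") -> np.ndarray:
    """High/low predicted-risk split: score strictly above the cohort mean.

    ``method='median'`` is available as the alternative reading of
    "above vs. below average". The center is always recomputed on the
    cohort being analysed, never carried over from training.
    """
    scores = np.asarray(per_eeg_scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least 2 EEGs to dichotomize risk")
    center = np.mean(scores) if method == "mean" else np.median(scores)
    return scores > center


@dataclass
class SurvivalResult:
    """Cox hazard ratios, KM curves per risk group, and the logrank test."""

    hazard_ratios: pd.DataFrame  # covariate, hr, ci_low, ci_high, p
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    survival_52w: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    logrank_stat: float = float("nan")
    logrank_p: float = float("nan")
    ph_violations: list[str] = field(default_factory=list)


def fit_cox(
    time_weeks: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
    penalizer: float = 0.0,
) -> SurvivalResult:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs.

    Continuous age is z-scored before the fit; categorical sex is encoded
    as an indicator. Proportionality is screened with the scaled-residual
    trend test and violations are logged, not fatal. Complete separation is
    retried with a small ridge penalty.
    """
    time_weeks = np.asarray(time_weeks, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    if (time_weeks < 0).any():
        raise ValueError("negative event times")
    if not event.any():
        raise ValueError("no observed events; Cox model is not identified")
    df = covariates.copy().reset_index(drop=True)
    if "age" in df.columns:
        sd = df["age"].std(ddof=0) or 1.0
        df["age"] = (df["age"] - df["age"].mean()) / sd
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "woman").astype(float)
    for col in df.columns:
        df[col] = df[col].astype(float)
    df["T"] = time_weeks
    df["E"] = event.astype(int)

    fitter = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="T", event_col="E")
    except ConvergenceError:
        logger.warning("fit_cox: convergence failure; refitting with ridge 1e-3")
        fitter = CoxPHFitter(penalizer=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="T", event_col="E")

    summary = fitter.summary
    hr = pd.DataFrame(
        {
            "covariate": summary.index,
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
            "log_hr": summary["coef"],
        }
    ).reset_index(drop=True)

    violations: list[str] = []
    try:
        from lifelines.statistics import proportional_hazard_test

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = proportional_hazard_test(fitter, df, time_transform="rank")
        for cov in ph.summary.index:
            if ph.summary.loc[cov, "p"] < 0.05:
                violations.append(str(cov))
                logger.warning("fit_cox: proportionality violation for %s", cov)
    except Exception:  # diagnostic only; never fail the fit
        logger.debug("fit_cox: proportionality screen unavailable", exc_info=True)
    return SurvivalResult(hazard_ratios=hr, ph_violations=violations)


def kaplan_meier(
    time_weeks: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
) -> SurvivalResult:
    """Product-limit curves per group with Greenwood CIs and a logrank test.

    One-year survival is read off each curve at 52 weeks. Empty groups are
    excluded with a warning.
    """
    time_weeks = np.asarray(time_weeks, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    curves: dict[str, pd.DataFrame] = {}
    s52: dict[str, tuple[float, float, float]] = {}
    for g in pd.unique(group):
        sel = group == g
        if not sel.any():
            logger.warning("kaplan_meier: empty group %r excluded", g)
            continue
        km = KaplanMeierFitter()
        km.fit(time_weeks[sel], event_observed=event[sel])
        ci = km.confidence_interval_survival_function_
        curve = pd.DataFrame(
            {
                "time_weeks": km.survival_function_.index.to_numpy(),
                "survival": km.survival_function_.iloc[:, 0].to_numpy(),
                "ci_low": ci.iloc[:, 0].to_numpy(),
                "ci_high": ci.iloc[:, 1].to_numpy(),
            }
        )
        curves[str(g)] = curve
        horizon = min(52.0, time_weeks[sel].max())
        idx = curve["time_weeks"].searchsorted(horizon, side="right") - 1
        idx = max(idx, 0)
        s52[str(g)] = (
            float(curve["survival"].iloc[idx]),
            float(curve["ci_low"].iloc[idx]),
            float(curve["ci_high"].iloc[idx]),
        )
    stat, p = np.nan, np.nan
    if len(curves) > 1:
        lr = multivariate_logrank_test(time_weeks, group.astype(str), event.astype(int))
        stat, p = float(lr.test_statistic), float(lr.p_value)
    return SurvivalResult(
        hazard_ratios=pd.DataFrame(),
        km_curves=curves,
        survival_52w=s52,
        logrank_stat=stat,
        logrank_p=p,
    )


# ---------------------------------------------------------------------------
# Binary metrics
# ---------------------------------------------------------------------------


def binary_metrics(
    per_eeg_scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> dict:
    """Sensitivity, specificity, PPV and NPV at a score threshold.

    Confidence intervals are exact (Clopper-Pearson) binomial intervals on
    each conditional proportion.
    """
    scores = np.asarray(per_eeg_scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("binary metrics require both classes")
    pred = scores > threshold
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))

    def ratio(num, den):
        if den == 0:
            return float("nan"), (float("nan"), float("nan"))
        lo, hi = proportion_confint(num, den, alpha=0.05, method="beta")
        return num / den, (float(lo), float(hi))

    sens, sens_ci = ratio(tp, tp + fn)
    spec, spec_ci = ratio(tn, tn + fp)
    ppv, ppv_ci = ratio(tp, tp + fp)
    npv, npv_ci = ratio(tn, tn + fn)
    return {
        "threshold": threshold,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "sensitivity": sens, "sensitivity_ci": sens_ci,
        "specificity": spec, "specificity_ci": spec_ci,
        "ppv": ppv, "ppv_ci": ppv_ci,
        "npv": npv, "npv_ci": npv_ci,
    }
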