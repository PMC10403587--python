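"""Classifier evaluation under patient-grouped nested cross-validation.

Epochs are the learning observations; every split (inner, outer, holdout)
keeps all epochs of a patient on one side. Epoch scores are aggregated per
EEG at a quantile (median by default) and all statistics — cross-validated
AUC with influence-function (LeDell-style) confidence intervals, holdout
AUC with DeLong intervals — are computed at the EEG level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import ModelSpec

logger = logging.getLogger(__name__)

OUTCOMES = ("recurrence_1y", "epilepsy_diagnosis", "active_epilepsy")


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Epoch-level design matrix with patient grouping and EEG-level labels."""

    X: pd.DataFrame  # rows = epochs
    eeg_ids: np.ndarray
    patient_ids: np.ndarray
    labels: np.ndarray  # per-epoch binary outcome
    age: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.X)
        for name in ("eeg_ids", "patient_ids", "labels"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match X")
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_epochs(self) -> int:
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.loc[mask],
            eeg_ids=self.eeg_ids[mask],
            patient_ids=self.patient_ids[mask],
            labels=self.labels[mask],
            age=None if self.age is None else self.age[mask],
        )


def outcome_labels(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """EEG-level binary labels for one of the three clinical outcomes."""
    if outcome == "recurrence_1y":
        lab = cohort["outcome_recurrence_1y"].astype(bool)
    elif outcome == "epilepsy_diagnosis":
        lab = cohort["epilepsy_type"].isin(["focal", "generalized", "unknown"])
    elif outcome == "active_epilepsy":
        lab = (
            cohort["epilepsy_type"].isin(["focal", "generalized", "unknown"])
            & cohort["outcome_recurrence_1y"].astype(bool)
        )
    else:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    return pd.Series(lab.to_numpy(), index=cohort["eeg_id"].to_numpy())


def build_feature_matrix(
    features: pd.DataFrame, cohort: pd.DataFrame, outcome: str = "recurrence_1y"
) -> FeatureMatrix:
    """Join an epoch-level feature table to the cohort's labels and grouping.

    ``features`` must be indexed by (eeg_id, epoch_index) as produced by
    :func:`eegprognosis.markers.tensor_to_features`.
    """
    labels = outcome_labels(cohort, outcome)
    meta = cohort.set_index("eeg_id")
    eeg_ids = features.index.get_level_values("eeg_id").to_numpy()
    missing = set(eeg_ids) - set(meta.index)
    if missing:
        raise ValueError(f"cohort table lacks rows for EEGs: {sorted(missing)[:5]}")
    return FeatureMatrix(
        X=features.reset_index(drop=True),
        eeg_ids=eeg_ids,
        patient_ids=meta.loc[eeg_ids, "patient_id"].to_numpy(),
        labels=labels.loc[eeg_ids].to_numpy().astype(int),
        age=meta.loc[eeg_ids, "age"].to_numpy(dtype=float)
        if "age" in meta.columns
        else None,
    )


# ---------------------------------------------------------------------------
# Grouped folds
# ---------------------------------------------------------------------------


def grouped_folds(patient_ids: Sequence, k: int, seed: int = 0) -> np.ndarray:
    """Fold index per row with every patient's rows in exactly one fold.

    Patients are shuffled with the seed and dealt round-robin, so fold sizes
    are balanced by patient count (within one).
    """
    patient_ids = np.asarray(patient_ids)
    unique = pd.unique(patient_ids)
    if len(unique) < k:
        raise ValueError(f"need at least k={k} distinct patients, got {len(unique)}")
    order = np.random.default_rng(seed).permutation(len(unique))
    fold_of = {unique[pi]: fi % k for fi, pi in enumerate(order)}
    return np.array([fold_of[p] for p in patient_ids], dtype=int)


# ---------------------------------------------------------------------------
# AUC and confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    """AUC point estimate with CI, inference method, and per-fold detail."""

    auc: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_eegs: int
    per_fold_aucs: list[float] = field(default_factory=list)
    p_vs_chance: float = float("nan")
    variance: float = float("nan")

    def __post_init__(self) -> None:
        self.ci_low = float(np.clip(self.ci_low, 0.0, min(1.0, self.auc)))
        self.ci_high = float(np.clip(self.ci_high, max(0.0, self.auc), 1.0))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC by midrank statistic; ties count one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = sstats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _placement_values(scores, labels):
    """DeLong structural components: P(control < case) placements."""
    cases = scores[labels]
    controls = scores[~labels]
    n1, n0 = cases.size, controls.size
    # V10_i: fraction of controls below case i (ties half)
    order = np.sort(controls)
    v10 = (
        np.searchsorted(order, cases, side="left")
        + 0.5 * (np.searchsorted(order, cases, side="right")
                 - np.searchsorted(order, cases, side="left"))
    ) / n0
    order = np.sort(cases)
    v01 = (
        n1
        - np.searchsorted(order, controls, side="right")
        + 0.5 * (np.searchsorted(order, controls, side="right")
                 - np.searchsorted(order, controls, side="left"))
    ) / n1
    return v10, v01


def auc_ci_delong(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> EvaluationResult:
    """Mann-Whitney AUC with DeLong structural-component variance."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    auc = mann_whitney_auc(scores, labels)
    v10, v01 = _placement_values(scores, labels)
    n1, n0 = v10.size, v01.size
    var = 0.0
    if n1 > 1:
        var += np.var(v10, ddof=1) / n1
    if n0 > 1:
        var += np.var(v01, ddof=1) / n0
    z = sstats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    se = np.sqrt(var)
    p = 2 * sstats.norm.sf(abs(auc - 0.5) / se) if se > 0 else (1.0 if auc == 0.5 else 0.0)
    return EvaluationResult(
        auc=auc,
        ci_low=auc - half,
        ci_high=auc + half,
        ci_method="delong",
        n_eegs=n1 + n0,
        per_fold_aucs=[auc],
        p_vs_chance=float(p),
        variance=float(var),
    )


def _influence_values(scores, labels, auc):
    """Hajek-projection influence values of the AUC within one fold."""
    labels = labels.astype(bool)
    cases = scores[labels]
    controls = scores[~labels]
    n1, n0 = cases.size, controls.size
    p1, p0 = n1 / (n1 + n0), n0 / (n1 + n0)
    v10, v01 = _placement_values(scores, labels)
    ic = np.empty(scores.size)
    ic[labels] = (v10 - auc) / p1
    ic[~labels] = (v01 - auc) / p0
    return ic


def auc_ci_ledell(
    per_eeg_scores: np.ndarray,
    labels: np.ndarray,
    fold_ids: np.ndarray,
    alpha: float = 0.05,
) -> EvaluationResult:
    """Cross-validated AUC with influence-function confidence interval.

    The point estimate is the mean of per-fold AUCs; its variance combines
    the fold-wise empirical variances of the AUC influence values plus the
    second-order U-statistic kernel term theta(1-theta)/(n1*n0), which is
    negligible asymptotically but material when folds hold only a few EEGs
    per class. When the minority class averages fewer than 8 EEGs per fold
    the variance is additionally floored by the Nadeau-Bengio corrected
    between-fold variance, (1/K + 1/(K-1)) * var(fold AUCs): fold AUCs are
    positively correlated through their shared training data, which the
    influence variance cannot see and which dominates in small cohorts.
    Folds containing a single class are excluded with a warning.
    """
    per_eeg_scores = np.asarray(per_eeg_scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    fold_ids = np.asarray(fold_ids)
    fold_aucs, fold_vars, fold_minority = [], [], []
    for fold in np.unique(fold_ids):
        sel = fold_ids == fold
        y = labels[sel]
        if y.all() or not y.any():
            logger.warning("auc_ci_ledell: fold %r has a single class; excluded", fold)
            continue
        s = per_eeg_scores[sel]
        auc_k = mann_whitney_auc(s, y)
        ic = _influence_values(s, y, auc_k)
        fold_aucs.append(auc_k)
        n1 = int(y.sum())
        n0 = int((~y).sum())
        fold_minority.append(min(n1, n0))
        second_order = auc_k * (1.0 - auc_k) / (n1 * n0)
        fold_vars.append(
            (np.var(ic, ddof=1) / ic.size if ic.size > 1 else 0.0) + second_order
        )
    if not fold_aucs:
        raise ValueError("no fold contains both classes")
    k = len(fold_aucs)
    cv_auc = float(np.mean(fold_aucs))
    var = float(np.sum(fold_vars)) / k**2
    if k > 1 and sum(fold_minority) < 8 * k:
        nb_floor = (1.0 / k + 1.0 / (k - 1)) * float(np.var(fold_aucs, ddof=1))
        var = max(var, nb_floor)
    se = np.sqrt(var)
    z = sstats.norm.ppf(1 - alpha / 2)
    p = 2 * sstats.norm.sf(abs(cv_auc - 0.5) / se) if se > 0 else (1.0 if cv_auc == 0.5 else 0.0)
    return EvaluationResult(
        auc=cv_auc,
        ci_low=cv_auc - z * se,
        ci_high=cv_auc + z * se,
        ci_method="ledell_cv",
        n_eegs=int(per_eeg_scores.size),
        per_fold_aucs=[float(a) for a in fold_aucs],
        p_vs_chance=float(p),
        variance=var,
    )


# ---------------------------------------------------------------------------
# Aggregation and variants
# ---------------------------------------------------------------------------


def aggregate_epoch_predictions(
    epoch_scores: pd.DataFrame, q: float = 0.5
) -> pd.Series:
    """Per-EEG empirical q-quantile (linear interpolation) of epoch scores.

    ``epoch_scores`` needs columns ``eeg_id`` and ``score``; EEGs with zero
    epochs simply do not appear. q=0.5 is the protocol's median default.
    """
    if not 0.1 <= q <= 0.9:
        raise ValueError("aggregation quantile must be in [0.1, 0.9]")
    return epoch_scores.groupby("eeg_id")["score"].quantile(q, interpolation="linear")


def two_step_classify(flags: np.ndarray, model_scores: np.ndarray) -> np.ndarray:
    """Clinical-flag override: flagged EEGs score 1.0, the rest keep the model."""
    flags = np.asarray(flags).astype(bool)
    model_scores = np.asarray(model_scores, dtype=np.float64)
    if flags.shape != model_scores.shape:
        raise ValueError("flags and scores must be aligned")
    return np.where(flags, 1.0, model_scores)


class AgeInteractionTransform:
    """Append scaled age and age x feature interactions (2p + 1 columns).

    Age statistics are fitted on the training rows only and reused on
    held-out rows.
    """

    def __init__(self) -> None:
        self.mean_: Optional[float] = None
        self.sd_: Optional[float] = None

    def fit(self, age: np.ndarray) -> "AgeInteractionTransform":
        age = self._check(age)
        self.mean_ = float(np.mean(age))
        sd = float(np.std(age))
        self.sd_ = sd if sd > 0 else 1.0
        return self

    @staticmethod
    def _check(age) -> np.ndarray:
        age = np.asarray(age, dtype=np.float64)
        if np.isnan(age).any():
            raise ValueError(
                f"missing age for rows {np.flatnonzero(np.isnan(age)).tolist()[:10]}"
            )
        return age

    def transform(self, X: pd.DataFrame, age: np.ndarray) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("fit before transform")
        age = self._check(age)
        scaled = (age - self.mean_) / self.sd_
        inter = X.to_numpy() * scaled[:, None]
        out = pd.concat(
            [
                X.reset_index(drop=True),
                pd.DataFrame({"age": scaled}),
                pd.DataFrame(
                    inter, columns=[f"age*{c}" for c in X.columns]
                ),
            ],
            axis=1,
        )
        out.index = X.index
        return out


def add_age_interactions(features: FeatureMatrix) -> FeatureMatrix:
    """Augment a feature matrix with its own age interactions (self-fitted)."""
    if features.age is None:
        raise ValueError("feature matrix has no age column")
    tf = AgeInteractionTransform().fit(features.age)
    return FeatureMatrix(
        X=tf.transform(features.X, features.age),
        eeg_ids=features.eeg_ids,
        patient_ids=features.patient_ids,
        labels=features.labels,
        age=features.age,
    )


# ---------------------------------------------------------------------------
# Feature selection and classifiers
# ---------------------------------------------------------------------------


class L1SVMSelector(BaseEstimator, TransformerMixin):
    """Columns with nonzero coefficients of an L1-penalized linear SVM.

    If the penalty kills every column the selector retains all of them and
    logs a warning (the documented fallback).
    """

    def __init__(self, C: float = 0.1, class_weighting: bool = True, seed: int = 0):
        self.C = C
        self.class_weighting = class_weighting
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("feature selection requires both classes")
        svm = LinearSVC(
            penalty="l1",
            dual=False,
            C=self.C,
            class_weight="balanced" if self.class_weighting else None,
            max_iter=3000,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svm.fit(X, y)
        mask = np.abs(svm.coef_).ravel() > 1e-10
        if not mask.any():
            logger.warning(
                "L1SVMSelector: no feature survived C=%g; retaining all", self.C
            )
            mask = np.ones(np.asarray(X).shape[1], dtype=bool)
        self.support_ = mask
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


def feature_select_l1svm(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    c: float = 0.1,
    class_weighting: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Boolean mask of columns retained by the L1-linear-SVM selector."""
    sel = L1SVMSelector(C=c, class_weighting=class_weighting, seed=seed)
    sel.fit(train_features, train_labels)
    return sel.support_


def make_classifier(algorithm: str, params: dict, class_weighting: bool, seed: int):
    params = dict(params)
    if algorithm == "glm_logistic_l1l2":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(
            penalty=params.get("penalty", "l2"),
            C=params.get("C", 1.0),
            solver="liblinear",
            max_iter=2000,
            tol=1e-4,
            class_weight="balanced" if class_weighting else None,
            random_state=seed,
        )
    if algorithm == "svm_rbf":
        from sklearn.svm import SVC

        return SVC(
            kernel="rbf",
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            probability=True,
            class_weight="balanced" if class_weighting else None,
            random_state=seed,
        )
    if algorithm == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 500),
            max_depth=params.get("max_depth"),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            class_weight="balanced" if class_weighting else None,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "gradient_boosted_trees":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=params.get("n_estimators", 200),
            learning_rate=params.get("learning_rate", 0.1),
            num_leaves=params.get("num_leaves", 31),
            class_weight="balanced" if class_weighting else None,
            random_state=seed,
            deterministic=True,
            n_jobs=1,
            verbose=-1,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _fit_and_score(X_train, y_train, X_test, combo, model_spec, seed):
    """Standardize -> L1-SVM select -> fit -> probabilistic scores on X_test."""
    fs_c, params = combo
    scaler = StandardScaler().fit(X_train)
    xt = scaler.transform(X_train)
    xv = scaler.transform(X_test)
    selector = L1SVMSelector(
        C=fs_c, class_weighting=model_spec.class_weighting, seed=seed
    ).fit(xt, y_train)
    xt = selector.transform(xt)
    xv = selector.transform(xv)
    clf = make_classifier(
        model_spec.algorithm, params, model_spec.class_weighting, seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(xt, y_train)
        return clf.predict_proba(xv)[:, 1]


# ---------------------------------------------------------------------------
# Prediction containers
# ---------------------------------------------------------------------------


@dataclass
class PredictionSet:
    """Epoch- and EEG-level prediction scores with fold provenance."""

    epoch_scores: pd.DataFrame  # eeg_id, patient_id, fold, score, label
    per_eeg: pd.DataFrame  # eeg_id, patient_id, fold, score, label
    quantile: float

    def fold_manifest(self) -> pd.DataFrame:
        return self.per_eeg[["eeg_id", "patient_id", "fold"]].copy()


def _aggregate(epoch_df: pd.DataFrame, q: float) -> pd.DataFrame:
    agg = epoch_df.groupby("eeg_id").agg(
        patient_id=("patient_id", "first"),
        fold=("fold", "first"),
        label=("label", "first"),
    )
    agg["score"] = aggregate_epoch_predictions(epoch_df, q)
    return agg.reset_index()


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


def _inner_select(train_fm: FeatureMatrix, model_spec, inner_k, q, seed):
    """Pick (fs C, hyperparameters) maximizing inner aggregated-AUC."""
    combos = [(fs_c, params) for fs_c in model_spec.fs_c_grid for params in model_spec.grid]
    if len(combos) == 1:
        return combos[0]
    inner_folds = grouped_folds(train_fm.patient_ids, inner_k, seed)
    X = train_fm.X.to_numpy()
    best_combo, best_auc = combos[0], -np.inf
    for combo in combos:
        frames = []
        for fold in range(inner_k):
            val = inner_folds == fold
            tr = ~val
            y_tr = train_fm.labels[tr]
            if len(np.unique(y_tr)) < 2 or not val.any():
                continue
            scores = _fit_and_score(X[tr], y_tr, X[val], combo, model_spec, seed)
            frames.append(
                pd.DataFrame(
                    {
                        "eeg_id": train_fm.eeg_ids[val],
                        "patient_id": train_fm.patient_ids[val],
                        "fold": fold,
                        "score": scores,
                        "label": train_fm.labels[val],
                    }
                )
            )
        if not frames:
            continue
        per_eeg = _aggregate(pd.concat(frames, ignore_index=True), q)
        try:
            auc = mann_whitney_auc(per_eeg["score"].to_numpy(), per_eeg["label"].to_numpy())
        except ValueError:
            continue
        if auc > best_auc:
            best_combo, best_auc = combo, auc
    return best_combo


def _impute_if_needed(train_X: pd.DataFrame, test_X: pd.DataFrame, seed: int):
    from .markers import impute_missing

    if train_X.isna().any().any() or test_X.isna().any().any():
        return impute_missing(train_X, test_X, seed=seed)
    return train_X, test_X


def _outer_folds_with_both_classes(fm: FeatureMatrix, outer_k: int, seed: int):
    labels_by_patient = pd.DataFrame(
        {"patient_id": fm.patient_ids, "label": fm.labels}
    ).groupby("patient_id")["label"].max()
    for attempt in range(10):
        folds = grouped_folds(fm.patient_ids, outer_k, seed + attempt)
        ok = True
        for fold in range(outer_k):
            y = fm.labels[folds == fold]
            if y.all() or not y.any():
                ok = False
                break
        if ok:
            if attempt:
                logger.info("outer folds refolded %d time(s) for class balance", attempt)
            return folds
    raise ValueError(
        "could not build outer folds with both classes in every fold "
        f"(10 attempts; class counts: {labels_by_patient.value_counts().to_dict()})"
    )


def nested_cv_evaluate(
    features: FeatureMatrix,
    model_spec: Optional[ModelSpec] = None,
    inner_k: int = 10,
    outer_k: int = 5,
    q: float = 0.5,
    seed: int = 0,
    fold_ids: Optional[np.ndarray] = None,
    variant: str = "plain",
    flags: Optional[pd.Series] = None,
) -> tuple[EvaluationResult, PredictionSet]:
    """Patient-grouped nested CV with per-EEG aggregation at quantile ``q``.

    The inner loop selects the L1-SVM selection strength and classifier
    hyperparameters by aggregated EEG-level AUC; outer-fold scores yield the
    cross-validated AUC with its influence-function CI. ``fold_ids`` injects
    a fixed outer-fold assignment (used to keep splits identical across
    marker subsets); ``variant`` may add age interactions or a two-step
    clinical-flag override (``flags`` indexed by eeg_id).
    """
    model_spec = model_spec or ModelSpec()
    if variant in ("two-step-ied", "two-step-lesion") and flags is None:
        raise ValueError(f"variant {variant!r} requires per-EEG flags")
    if fold_ids is None:
        fold_ids = _outer_folds_with_both_classes(features, outer_k, seed)
    else:
        fold_ids = np.asarray(fold_ids, dtype=int)
        if fold_ids.shape[0] != features.n_epochs:
            raise ValueError("fold_ids length must equal the number of epochs")
        outer_k = int(fold_ids.max()) + 1

    frames = []
    for fold in range(outer_k):
        test = fold_ids == fold
        train = ~test
        train_fm = features.subset(train)
        train_X, test_X = _impute_if_needed(train_fm.X, features.X.loc[test], seed)
        age_tf = None
        if variant == "age-interaction":
            if features.age is None:
                raise ValueError("age-interaction variant requires age")
            age_tf = AgeInteractionTransform().fit(train_fm.age)
            train_X = age_tf.transform(train_X, train_fm.age)
            test_X = age_tf.transform(test_X, features.age[test])
        inner_fm = FeatureMatrix(
            X=train_X,
            eeg_ids=train_fm.eeg_ids,
            patient_ids=train_fm.patient_ids,
            labels=train_fm.labels,
            age=train_fm.age,
        )
        eff_inner_k = min(inner_k, len(pd.unique(inner_fm.patient_ids)))
        combo = _inner_select(inner_fm, model_spec, eff_inner_k, q, seed)
        scores = _fit_and_score(
            train_X.to_numpy(), train_fm.labels, test_X.to_numpy(),
            combo, model_spec, seed,
        )
        frames.append(
            pd.DataFrame(
                {
                    "eeg_id": features.eeg_ids[test],
                    "patient_id": features.patient_ids[test],
                    "fold": fold,
                    "score": scores,
                    "label": features.labels[test],
                }
            )
        )
    epoch_df = pd.concat(frames, ignore_index=True)
    per_eeg = _aggregate(epoch_df, q)
    if variant in ("two-step-ied", "two-step-lesion"):
        flag_vals = flags.reindex(per_eeg["eeg_id"]).to_numpy()
        per_eeg["score"] = two_step_classify(flag_vals, per_eeg["score"].to_numpy())
    result = auc_ci_ledell(
        per_eeg["score"].to_numpy(),
        per_eeg["label"].to_numpy(),
        per_eeg["fold"].to_numpy(),
    )
    return result, PredictionSet(epoch_scores=epoch_df, per_eeg=per_eeg, quantile=q)


# ---------------------------------------------------------------------------
# Temporally shifted holdout
# ---------------------------------------------------------------------------


def holdout_evaluate(
    train_features: FeatureMatrix,
    test_features: FeatureMatrix,
    model_spec: Optional[ModelSpec] = None,
    q: float = 0.5,
    inner_k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[EvaluationResult, PredictionSet, dict]:
    """Train-once / test-once protocol with DeLong CI and binary metrics.

    Hyperparameters and the feature subset are selected by grouped CV on the
    training split alone; the refit model scores the held-out split, scores
    are aggregated per EEG, and sensitivity/specificity/PPV/NPV are reported
    at the 0.5 threshold. Overlapping patients between splits are an error.
    """
    model_spec = model_spec or ModelSpec()
    overlap = set(train_features.patient_ids) & set(test_features.patient_ids)
    if overlap:
        raise ValueError(
            f"patients present in both splits: {sorted(overlap)[:5]}"
        )
    train_X, test_X = _impute_if_needed(train_features.X, test_features.X, seed)
    inner_fm = FeatureMatrix(
        X=train_X,
        eeg_ids=train_features.eeg_ids,
        patient_ids=train_features.patient_ids,
        labels=train_features.labels,
        age=train_features.age,
    )
    eff_inner_k = min(inner_k, len(pd.unique(inner_fm.patient_ids)))
    combo = _inner_select(inner_fm, model_spec, eff_inner_k, q, seed)
    scores = _fit_and_score(
        train_X.to_numpy(), train_features.labels, test_X.to_numpy(),
        combo, model_spec, seed,
    )
    epoch_df = pd.DataFrame(
        {
            "eeg_id": test_features.eeg_ids,
            "patient_id": test_features.patient_ids,
            "fold": 0,
            "score": scores,
            "label": test_features.labels,
        }
    )
    per_eeg = _aggregate(epoch_df, q)
    result = auc_ci_delong(per_eeg["score"].to_numpy(), per_eeg["label"].to_numpy())
    from .posthoc import binary_metrics

    metrics = binary_metrics(
        per_eeg["score"].to_numpy(), per_eeg["label"].to_numpy(), threshold=threshold
    )
    return result, PredictionSet(epoch_scores=epoch_df, per_eeg=per_eeg, quantile=q), metrics
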