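"""Built-in validation studies with known ground truth.

Each study runs the package end to end against synthetic data whose true
structure is known and returns the measured quantities as plain floats:
oracle equivalence of the entropy estimators, marker sanity properties,
null calibration and effect recovery of the nested cross-validation,
patient-leakage audits, AUC-inference coverage, the two-step rule, survival
recovery, and bitwise rerun determinism. ``scripts/acceptance.py`` and the
test-suite both drive these functions.

The study sizes are deliberately desk-scale (tens of patients, a few epochs
per recording, reduced hyperparameter grids); docs/methods.md records them.

The naive reference implementations in this module (``naive_*``,
``pair_counting_auc``) are written independently of the production kernels —
explicit embedding matrices and O(N^2) Python/numpy loops — and serve as the
oracles the fast implementations are compared against.
"""

from __future__ import annotations

import json
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import (
    AnnotationSchedule,
    EntropyParams,
    ModelSpec,
    SimulationConfig,
    SurvivalParams,
    WaveletSpec,
)
from .evaluation import (
    FeatureMatrix,
    auc_ci_delong,
    auc_ci_ledell,
    build_feature_matrix,
    grouped_folds,
    holdout_evaluate,
    nested_cv_evaluate,
    two_step_classify,
)
from .markers import entropy, extract_marker_tensor, tensor_to_features
from .preprocessing import (
    extract_epochs,
    filter_recording,
    fit_rejection_thresholds,
    repair_epochs,
    to_average_reference,
)
from .synthetic import (
    fractional_gaussian_noise,
    simulate_cohort_table,
    simulate_outcomes,
    simulate_recording,
)


def _seed(base: int, k: int) -> int:
    return int((base * 100003 + k * 7919 + 17) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Naive reference implementations (oracles)
# ---------------------------------------------------------------------------


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    return np.array([x[i : i + (m - 1) * tau + 1 : tau] for i in range(n)])


def naive_apen(x: np.ndarray, params: EntropyParams, r_abs: float) -> float:
    def phi(m):
        emb = _embed(x, m, params.tau)
        d = cdist(emb, emb, metric="chebyshev")
        c = (d <= r_abs).sum(axis=1) / emb.shape[0]
        return np.mean(np.log(c))

    return float(phi(params.m) - phi(params.m + 1))


def naive_sampen(x: np.ndarray, params: EntropyParams, r_abs: float) -> float:
    m, tau = params.m, params.tau
    n = x.size - m * tau
    emb_m = _embed(x, m, tau)[:n]
    emb_m1 = _embed(x, m + 1, tau)
    dm = cdist(emb_m, emb_m, metric="chebyshev")
    dm1 = cdist(emb_m1, emb_m1, metric="chebyshev")
    iu = np.triu_indices(n, k=1)
    b = int((dm[iu] <= r_abs).sum())
    a = int((dm1[iu] <= r_abs).sum())
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def naive_fuzzen(x: np.ndarray, params: EntropyParams, r_abs: float) -> float:
    m, tau = params.m, params.tau
    n = x.size - m * tau

    def phi(dim):
        emb = _embed(x, dim, tau)[:n]
        emb = emb - emb.mean(axis=1, keepdims=True)
        d = cdist(emb, emb, metric="chebyshev")
        iu = np.triu_indices(n, k=1)
        return float(np.mean(np.exp(-((d[iu] / r_abs) ** params.n))))

    pm, pm1 = phi(m), phi(m + 1)
    if pm <= 0 or pm1 <= 0:
        return float("nan")
    return float(np.log(pm) - np.log(pm1))


def naive_permen(x: np.ndarray, params: EntropyParams) -> float:
    from collections import Counter

    k, tau = params.k, params.tau
    patterns = Counter()
    for i in range(x.size - (k - 1) * tau):
        window = x[i : i + (k - 1) * tau + 1 : tau]
        # stable argsort ranks with ties broken by occurrence order
        order = tuple(np.argsort(window, kind="stable"))
        patterns[order] += 1
    total = sum(patterns.values())
    p = np.array([c / total for c in patterns.values()])
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(k)))


def pair_counting_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force AUC: all case-control pairs, ties count one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    cases = scores[labels]
    controls = scores[~labels]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (cases.size * controls.size)


# ---------------------------------------------------------------------------
# Study 1: entropy oracle equivalence
# ---------------------------------------------------------------------------


def entropy_oracle_study(seed: int = 0, n_series: int = 12) -> dict:
    """Fast estimators vs naive template-counting on short random series."""
    rng = np.random.default_rng(_seed(seed, 1))
    params = EntropyParams()
    max_diff = 0.0
    n_checked = 0
    for i in range(n_series):
        n = int(rng.integers(40, 101))
        if i % 3 == 0:
            x = rng.standard_normal(n)
        elif i % 3 == 1:
            x = np.sin(np.arange(n) * 0.3) + 0.3 * rng.standard_normal(n)
        else:
            x = np.round(rng.standard_normal(n), 1)  # ties
        r_abs = params.r * x.std()
        pairs = [
            (entropy(x, "approximate", params), naive_apen(x, params, r_abs)),
            (entropy(x, "sample", params), naive_sampen(x, params, r_abs)),
            (entropy(x, "fuzzy", params), naive_fuzzen(x, params, r_abs)),
            (entropy(x, "permutation", params), naive_permen(x, params)),
        ]
        for fast, slow in pairs:
            if np.isnan(fast) and np.isnan(slow):
                continue
            max_diff = max(max_diff, abs(fast - slow))
            n_checked += 1
    return {"entropy_oracle_max_abs_diff": {"value": float(max_diff), "n": n_checked}}


# ---------------------------------------------------------------------------
# Study 2: marker sanity
# ---------------------------------------------------------------------------


def marker_sanity_study(seed: int = 0) -> dict:
    from .markers import hurst_exponent, line_length, wavelet_decompose

    rng = np.random.default_rng(_seed(seed, 2))
    params = EntropyParams()
    out: dict = {}

    out["permen_monotone_series"] = {
        "value": float(entropy(np.arange(200.0), "permutation", params)),
        "n": 200,
    }

    t = np.arange(2000) / 200.0
    sine = np.sin(2 * np.pi * 10 * t)
    spec_noise = entropy(rng.standard_normal(2000), "spectral", params, fs=200.0)
    spec_sine = entropy(sine, "spectral", params, fs=200.0)
    out["specen_noise_minus_sine"] = {"value": float(spec_noise - spec_sine), "n": 2000}

    wins = 0
    for k in range(30):
        r2 = np.random.default_rng(_seed(seed, 100 + k))
        noise = r2.standard_normal(2000)
        phase = r2.uniform(0, 2 * np.pi)
        s = np.sin(2 * np.pi * 10 * t + phase)
        s = s / s.std()
        if entropy(noise / noise.std(), "sample", params) > entropy(s, "sample", params):
            wins += 1
    out["sampen_noise_gt_sine_count"] = {"value": float(wins), "n": 30}

    x = rng.standard_normal(500)
    out["ll_homogeneity_rel_err"] = {
        "value": float(abs(line_length(3.5 * x) - 3.5 * line_length(x))
                       / (3.5 * line_length(x))),
        "n": 500,
    }

    sigx = rng.standard_normal(2048)
    levels = wavelet_decompose(sigx, WaveletSpec())
    import pywt

    coeffs = pywt.wavedec(sigx, "sym5", mode="periodization", level=6)
    total = sum(float(np.sum(c**2)) for c in coeffs)
    out["wavelet_energy_rel_err"] = {
        "value": float(abs(total - np.sum(sigx**2)) / np.sum(sigx**2)),
        "n": 2048,
    }
    del levels

    for h, label in ((0.3, "hurst_h03_mean"), (0.7, "hurst_h07_mean")):
        ests = [
            hurst_exponent(
                fractional_gaussian_noise(h, 2000, np.random.default_rng(_seed(seed, 200 + i)))
            )
            for i in range(30)
        ]
        out[label] = {"value": float(np.mean(ests)), "n": 30}
    return out


# ---------------------------------------------------------------------------
# Synthetic-feature helper for the CV studies
# ---------------------------------------------------------------------------


def synthesize_features(
    n_patients: int,
    seed: int,
    effects: Optional[dict] = None,
    markers: Optional[Sequence[str]] = None,
    n_epochs: int = 3,
    prevalence: float = 0.3,
    test_fraction: float = 0.0,
    min_class_size: int = 0,
    ied_rates: Optional[tuple[float, float]] = None,
    n_channels: int = 19,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort, preprocess, extract markers; return (cohort, wide).

    Recordings carry only montage-change annotations (one epoch each, spaced
    30 s) to keep the study tractable; preprocessing (filter, average
    reference, CV thresholds with 3 folds, spline repair) runs in full.
    ``min_class_size`` redraws the clinical table (bumping the seed) until
    both outcome classes have at least that many patients — the nested-CV
    precondition — before any signal is synthesized.
    """
    duration = 30.0 * n_epochs + 20.0
    sched = AnnotationSchedule(
        montage_interval_s=30.0, hv_start_s=None, photic_freqs_hz=None,
        eye_interval_s=None,
    )
    for attempt in range(50):
        config = SimulationConfig(
            n_patients=n_patients,
            prevalence_recurrence=prevalence,
            duration_s=duration,
            schedule=sched,
            effect_sizes=effects if effects is not None else {},
            seed=_seed(seed, 977 * attempt) if attempt else seed,
            test_fraction=test_fraction,
            n_channels=n_channels,
        )
        if ied_rates is not None:
            config.ied_rate_positive, config.ied_rate_negative = ied_rates
        cohort = simulate_cohort_table(config)
        n_cases = int(cohort["outcome_recurrence_1y"].sum())
        if min(n_cases, len(cohort) - n_cases) >= min_class_size:
            break
    all_epochs = []
    labels = None
    for _, row in cohort.iterrows():
        rec = simulate_recording(row, config)
        rec = to_average_reference(filter_recording(rec))
        eps = extract_epochs(rec)
        if len(eps) >= 3:
            thr = fit_rejection_thresholds(eps, k_folds=3)
            eps = repair_epochs(eps, thr, rec.channel_labels)
        labels = rec.channel_labels
        all_epochs.extend(eps)
    tensor = extract_marker_tensor(all_epochs, labels, markers=markers)
    return cohort, tensor_to_features(tensor)


# ---------------------------------------------------------------------------
# Study 3: null calibration
# ---------------------------------------------------------------------------

_NULL_SPEC = ModelSpec(
    algorithm="glm_logistic_l1l2",
    grid=[{"penalty": "l2", "C": 0.1}, {"penalty": "l2", "C": 1.0}],
    fs_c_grid=(0.1,),
)


def null_calibration_study(seed: int = 0, n_reps: int = 20) -> dict:
    """Permuted-label nested CV (10-inner/5-outer) on 60-patient cohorts.

    Each repetition draws a fresh cohort with no class-dependent structure
    (zero effect sizes, equal spike-wave rates) and permutes its labels at
    the patient level, making the repetitions an exact, independent null:
    permutations of a single shared cohort would co-vary through that
    cohort's chance structure, and class-dependent generation would leak
    true signal into the permuted labels via their chance overlap.
    """
    aucs, covered = [], 0
    for rep in range(n_reps):
        cohort, features = synthesize_features(
            60, _seed(seed, 3000 + rep), effects={}, markers=("PAF",),
            n_epochs=4, min_class_size=5, ied_rates=(0.3, 0.3),
        )
        fm = build_feature_matrix(features, cohort)
        patients = pd.unique(fm.patient_ids)
        label_of = (
            pd.DataFrame({"p": fm.patient_ids, "y": fm.labels})
            .groupby("p")["y"].first()
        )
        rng = np.random.default_rng(_seed(seed, 300 + rep))
        permuted = pd.Series(
            rng.permutation(label_of.loc[patients].to_numpy()), index=patients
        )
        fm_perm = FeatureMatrix(
            X=fm.X,
            eeg_ids=fm.eeg_ids,
            patient_ids=fm.patient_ids,
            labels=permuted.loc[fm.patient_ids].to_numpy(),
            age=fm.age,
        )
        res, _ = nested_cv_evaluate(
            fm_perm, _NULL_SPEC, inner_k=10, outer_k=5, seed=_seed(seed, 400 + rep)
        )
        aucs.append(res.auc)
        if res.ci_low <= 0.5 <= res.ci_high:
            covered += 1
    return {
        "null_cv_mean_auc": {"value": float(np.mean(aucs)), "n": n_reps},
        "null_ci_coverage_rate": {"value": covered / n_reps, "n": n_reps},
    }


# ---------------------------------------------------------------------------
# Study 4: effect recovery (classifiers + marker ranking)
# ---------------------------------------------------------------------------

_EFFECT_SPECS = {
    "glm_logistic_l1l2": ModelSpec(
        "glm_logistic_l1l2",
        grid=[{"penalty": "l2", "C": 1.0}, {"penalty": "l1", "C": 1.0}],
        fs_c_grid=(0.1,),
    ),
    "svm_rbf": ModelSpec(
        "svm_rbf",
        grid=[{"C": 1.0, "gamma": "scale"}, {"C": 10.0, "gamma": "scale"}],
        fs_c_grid=(0.1,),
    ),
    "random_forest": ModelSpec(
        "random_forest",
        grid=[
            {"n_estimators": 200, "max_depth": None, "min_samples_leaf": 1},
            {"n_estimators": 200, "max_depth": None, "min_samples_leaf": 5},
        ],
        fs_c_grid=(0.1,),
    ),
    "gradient_boosted_trees": ModelSpec(
        "gradient_boosted_trees",
        grid=[
            {"n_estimators": 150, "learning_rate": 0.1, "num_leaves": 15},
            {"n_estimators": 150, "learning_rate": 0.1, "num_leaves": 31},
        ],
        fs_c_grid=(0.1,),
    ),
}

_SHORT_NAME = {
    "glm_logistic_l1l2": "glm",
    "svm_rbf": "svm",
    "random_forest": "rf",
    "gradient_boosted_trees": "gbt",
}


def effect_recovery_study(seed: int = 0) -> dict:
    """All four classifiers on a cohort with d=1.5 injected in all families."""
    cohort, features = synthesize_features(
        40,
        _seed(seed, 4),
        effects={"band_power": 1.5, "paf_hz": -1.5, "entropy": 1.5},
        n_epochs=3,
        prevalence=0.4,
        min_class_size=5,
    )
    fm = build_feature_matrix(features, cohort)
    out = {}
    for algo, spec in _EFFECT_SPECS.items():
        res, _ = nested_cv_evaluate(
            fm, spec, inner_k=3, outer_k=5, seed=_seed(seed, 5)
        )
        out[f"effect_auc_{_SHORT_NAME[algo]}"] = {
            "value": float(res.auc), "n": res.n_eegs,
        }
    return out


def marker_ranking_study(seed: int = 0, n_seeds: int = 10) -> dict:
    """Band-power-only injection: BP should rank first among the ten markers.

    The injected contrast is the power-neutral sliding-beta family
    (``bp_contrast``), constructed so that band power carries the class
    signal while level energies and spectral shape stay flat.
    """
    from .posthoc import compare_markers
    from .markers import MARKER_NAMES

    spec = ModelSpec(
        "glm_logistic_l1l2",
        grid=[{"penalty": "l2", "C": 0.1}],
        fs_c_grid=(0.1,),
    )
    wins = 0
    for rep in range(n_seeds):
        cohort, features = synthesize_features(
            24,
            _seed(seed, 600 + rep),
            effects={"bp_contrast": 1.5},
            n_epochs=2,
            prevalence=0.4,
            min_class_size=5,
            n_channels=10,
        )
        by_marker = {}
        for marker in MARKER_NAMES:
            cols = [c for c in features.columns if c.split("|")[1] == marker]
            sub = features[cols]
            by_marker[marker] = build_feature_matrix(sub, cohort)
        table = compare_markers(
            by_marker,
            spec,
            inner_k=3,
            outer_k=4,
            seed=_seed(seed, 700 + rep),
            include_union=False,
        )
        best = table.iloc[0]["marker"]
        if best == "BP":
            wins += 1
    return {"marker_ranking_bp_first_rate": {"value": wins / n_seeds, "n": n_seeds}}


# ---------------------------------------------------------------------------
# Study 5: leakage audit
# ---------------------------------------------------------------------------


def leakage_audit_study(seed: int = 0) -> dict:
    """Zero patient overlap across nested folds and the temporal holdout."""
    rng = np.random.default_rng(_seed(seed, 6))
    n_patients = 40
    patient_ids = np.repeat([f"P{i:03d}" for i in range(n_patients)], 3)
    x = pd.DataFrame(rng.standard_normal((patient_ids.size, 12)))
    labels_by_patient = rng.integers(0, 2, n_patients)
    labels = np.repeat(labels_by_patient, 3)
    fm = FeatureMatrix(
        X=x,
        eeg_ids=np.repeat([f"E{i:03d}" for i in range(n_patients)], 3),
        patient_ids=patient_ids,
        labels=labels,
    )
    spec = ModelSpec(
        "glm_logistic_l1l2", grid=[{"penalty": "l2", "C": 1.0}], fs_c_grid=(0.1,)
    )
    _, preds = nested_cv_evaluate(fm, spec, inner_k=3, outer_k=5, seed=_seed(seed, 7))
    manifest = preds.per_eeg
    violations = 0
    per_patient_folds = manifest.groupby("patient_id")["fold"].nunique()
    violations += int((per_patient_folds > 1).sum())
    folds = grouped_folds(fm.patient_ids, 5, _seed(seed, 7))
    for fold in range(5):
        train_p = set(fm.patient_ids[folds != fold])
        test_p = set(fm.patient_ids[folds == fold])
        violations += len(train_p & test_p)
    # temporal holdout: disjoint split evaluates; overlapping split must raise
    train_mask = np.isin(fm.patient_ids, [f"P{i:03d}" for i in range(28)])
    _res, hpreds, _m = holdout_evaluate(
        fm.subset(train_mask), fm.subset(~train_mask), spec, inner_k=3,
        seed=_seed(seed, 8),
    )
    violations += len(
        set(fm.patient_ids[train_mask]) & set(hpreds.per_eeg["patient_id"])
    )
    try:
        holdout_evaluate(fm.subset(train_mask), fm, spec, seed=0)
        violations += 1  # overlap silently accepted
    except ValueError:
        pass
    return {"leakage_overlap_count": {"value": float(violations), "n": n_patients}}


# ---------------------------------------------------------------------------
# Study 6: AUC inference (DeLong oracle + CI coverage)
# ---------------------------------------------------------------------------


def auc_inference_study(seed: int = 0, n_reps: int = 500) -> dict:
    rng = np.random.default_rng(_seed(seed, 9))
    max_diff = 0.0
    for _ in range(20):
        n = int(rng.integers(10, 51))
        y = np.zeros(n, dtype=int)
        y[: max(1, n // 3)] = 1
        rng.shuffle(y)
        s = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        res = auc_ci_delong(s, y)
        max_diff = max(max_diff, abs(res.auc - pair_counting_auc(s, y)))

    true_auc = 0.75
    # binormal model: AUC = Phi(mu/sqrt(2)) -> mu = sqrt(2) * Phi^{-1}(0.75)
    mu = math.sqrt(2.0) * 0.6744897501960817
    n1, n0 = 60, 140
    delong_cov = 0
    ledell_cov = 0
    for rep in range(n_reps):
        r = np.random.default_rng(_seed(seed, 1000 + rep))
        scores = np.concatenate([r.standard_normal(n1) + mu, r.standard_normal(n0)])
        labels = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
        res = auc_ci_delong(scores, labels)
        if res.ci_low <= true_auc <= res.ci_high:
            delong_cov += 1
        folds = grouped_folds(np.arange(n1 + n0), 5, _seed(seed, 2000 + rep))
        resl = auc_ci_ledell(scores, labels, folds)
        if resl.ci_low <= true_auc <= resl.ci_high:
            ledell_cov += 1
    return {
        "delong_oracle_max_abs_diff": {"value": float(max_diff), "n": 20},
        "delong_ci_coverage": {"value": delong_cov / n_reps, "n": n_reps},
        "ledell_ci_coverage": {"value": ledell_cov / n_reps, "n": n_reps},
    }


# ---------------------------------------------------------------------------
# Study 7: two-step rule
# ---------------------------------------------------------------------------


def two_step_study(seed: int = 0, n: int = 1000) -> dict:
    """Flags perfectly encode a subset of cases; the model is informative on
    the rest; the combined rule should beat both components."""
    rng = np.random.default_rng(_seed(seed, 10))
    labels = (rng.uniform(size=n) < 0.35).astype(int)
    flags = (labels == 1) & (rng.uniform(size=n) < 0.4)  # subset of cases only
    model_scores = np.clip(
        0.4 + 0.25 * labels + 0.15 * rng.standard_normal(n), 0.0, 1.0
    )
    combined = two_step_classify(flags, model_scores)
    return {
        "two_step_auc": {"value": auc_ci_delong(combined, labels).auc, "n": n},
        "two_step_model_only_auc": {
            "value": auc_ci_delong(model_scores, labels).auc, "n": n,
        },
        "two_step_flag_only_auc": {
            "value": auc_ci_delong(flags.astype(float), labels).auc, "n": n,
        },
    }


# ---------------------------------------------------------------------------
# Study 8: survival recovery
# ---------------------------------------------------------------------------


def survival_recovery_study(seed: int = 0, n_reps: int = 200, n: int = 500) -> dict:
    from .posthoc import fit_cox, kaplan_meier

    log_hrs = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_seed(seed, 3000 + rep))
        group = rng.integers(0, 2, n).astype(float)
        params = SurvivalParams(
            baseline_hazard_per_week=0.01, log_hazard_per_risk=math.log(2.0)
        )
        surv = simulate_outcomes(group, params, rng)
        cov = pd.DataFrame(
            {
                "risk_group": group,
                "age": rng.normal(50, 15, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "asm_count": rng.poisson(1.0, n).astype(float),
            }
        )
        res = fit_cox(
            surv["time_to_event_weeks"].to_numpy(),
            surv["event_observed"].to_numpy(),
            cov,
        )
        row = res.hazard_ratios.set_index("covariate").loc["risk_group"]
        log_hrs.append(float(row["log_hr"]))

    lam = 0.01
    km_cov = 0
    n_km = 300
    for rep in range(n_reps):
        rng = np.random.default_rng(_seed(seed, 4000 + rep))
        params = SurvivalParams(baseline_hazard_per_week=lam, log_hazard_per_risk=0.0)
        surv = simulate_outcomes(np.zeros(n_km), params, rng)
        km = kaplan_meier(
            surv["time_to_event_weeks"].to_numpy(),
            surv["event_observed"].to_numpy(),
            np.zeros(n_km, dtype=int),
        )
        s, lo, hi = km.survival_52w["0"]
        if lo <= math.exp(-52.0 * lam) <= hi:
            km_cov += 1
    return {
        "cox_mean_log_hr": {"value": float(np.mean(log_hrs)), "n": n_reps},
        "km_greenwood_coverage": {"value": km_cov / n_reps, "n": n_reps},
    }


# ---------------------------------------------------------------------------
# Study 9: end-to-end determinism
# ---------------------------------------------------------------------------


def determinism_study(seed: int = 0, work_dir: Optional[str] = None) -> dict:
    """Full pipeline run twice with one config/seed; numbers must agree."""
    import tempfile
    from .config import EvaluationParams, RunConfig
    from .pipeline import run_pipeline

    def one_run(out_dir: str) -> dict:
        sched = AnnotationSchedule(
            montage_interval_s=30.0, hv_start_s=None, photic_freqs_hz=None,
            eye_interval_s=None,
        )
        config = RunConfig(
            out_dir=out_dir,
            seed=_seed(seed, 11),
            simulation=SimulationConfig(
                n_patients=16,
                prevalence_recurrence=0.45,
                duration_s=120.0,
                schedule=sched,
                test_fraction=0.25,
                seed=_seed(seed, 11),
            ),
            evaluation=EvaluationParams(outer_k=4, inner_k=3),
            markers=("BP", "PAF"),
        )
        paths = run_pipeline(config)
        ev = json.loads(open(paths["evaluation"]).read())
        ph = json.loads(open(paths["posthoc"]).read())
        return {"evaluation": ev, "posthoc": ph}

    def numbers(obj, out):
        if isinstance(obj, dict):
            for v in obj.values():
                numbers(v, out)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                numbers(v, out)
        elif isinstance(obj, (int, float)) and not isinstance(obj, bool):
            out.append(float(obj))
        return out

    with tempfile.TemporaryDirectory(dir=work_dir) as td:
        a = one_run(f"{td}/run_a")
        b = one_run(f"{td}/run_b")
    na = np.array(numbers(a, []))
    nb = np.array(numbers(b, []))
    if na.size != nb.size:
        diff = float("inf")
    else:
        with np.errstate(invalid="ignore"):
            both_nan = np.isnan(na) & np.isnan(nb)
            diff_arr = np.abs(na - nb)
            diff_arr[both_nan] = 0.0
            diff = float(np.nanmax(diff_arr)) if diff_arr.size else 0.0
    return {"pipeline_rerun_max_abs_diff": {"value": diff, "n": int(na.size)}}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

ALL_STUDIES = (
    entropy_oracle_study,
    marker_sanity_study,
    null_calibration_study,
    effect_recovery_study,
    marker_ranking_study,
    leakage_audit_study,
    auc_inference_study,
    two_step_study,
    survival_recovery_study,
    determinism_study,
)


def run_all_studies(seed: int = 0, verbose: bool = True) -> dict:
    import time

    results: dict = {}
    for study in ALL_STUDIES:
        t0 = time.time()
        results.update(study(seed))
        if verbose:
            print(f"  {study.__name__}: {time.time() - t0:.1f} s", flush=True)
    return results
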