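"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate -> preprocess -> extract -> evaluate ->
posthoc with one manifest per stage (counts in/out, seed, parameters) so a
run is auditable and any stage can be rerun from its serialized inputs.
All randomness descends from ``config.seed``; a rerun with the same config
reproduces every number bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .config import ModelSpec, RunConfig
from .evaluation import build_feature_matrix, holdout_evaluate, nested_cv_evaluate
from .markers import extract_marker_tensor, tensor_to_features
from .posthoc import (
    SubgroupSpec,
    SUBGROUP_VARIABLES,
    dichotomize_risk,
    fit_cox,
    kaplan_meier,
    subgroup_auc,
)
from .preprocessing import (
    extract_epochs,
    filter_recording,
    fit_rejection_thresholds,
    repair_epochs,
    to_average_reference,
)
from .synthetic import iter_recordings, simulate_cohort_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _write_manifest(out_dir: Path, stage: str, payload: dict) -> None:
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2))


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                logger.info("stage=%s status=start", name)
                out = fn(*args, **kwargs)
                logger.info("stage=%s status=done", name)
                return out
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return run
    return wrap


@_stage("simulate")
def simulate_stage(config: RunConfig, out_dir: Path) -> Path:
    sim = config.simulation
    table = simulate_cohort_table(sim)
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for rec in iter_recordings(table, sim):
        eio.write_edf(rec, rec_dir / f"{rec.eeg_id}.edf")
        n += 1
    cohort_path = out_dir / "cohort.tsv"
    eio.write_cohort_tsv(table, cohort_path)
    _write_manifest(out_dir, "simulate", {
        "seed": sim.seed, "n_patients": int(len(table)), "n_recordings": n,
    })
    logger.info("stage=simulate patients=%d recordings=%d", len(table), n)
    return cohort_path


@_stage("preprocess")
def preprocess_stage(config: RunConfig, out_dir: Path) -> Path:
    cohort_path = out_dir / "cohort.tsv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"cohort table not found: {cohort_path}")
    cohort = eio.read_cohort_tsv(cohort_path)
    pp = config.preprocessing
    all_epochs = []
    channel_labels = None
    counts = {"recordings": 0, "epochs_extracted": 0, "epochs_kept": 0}
    for eeg_id in cohort["eeg_id"]:
        rec = eio.read_edf(out_dir / "recordings" / f"{eeg_id}.edf")
        rec = filter_recording(rec, pp.hp_cutoff_hz, pp.notch_hz)
        rec = to_average_reference(rec)
        epochs = extract_epochs(rec, pp.epoch_len_s)
        channel_labels = rec.channel_labels
        if len(epochs) >= pp.k_folds:
            thresholds = fit_rejection_thresholds(
                epochs, k_folds=pp.k_folds, n_candidates=pp.n_threshold_candidates
            )
            kept = repair_epochs(
                epochs, thresholds, rec.channel_labels, pp.max_bad_fraction
            )
        else:
            kept = epochs
        counts["recordings"] += 1
        counts["epochs_extracted"] += len(epochs)
        counts["epochs_kept"] += len(kept)
        all_epochs.extend(kept)
        logger.info(
            "stage=preprocess eeg_id=%s epochs_in=%d epochs_out=%d",
            eeg_id, len(epochs), len(kept),
        )
    store = out_dir / "epochs.tsv.gz"
    eio.write_epoch_store(all_epochs, channel_labels, store)
    _write_manifest(out_dir, "preprocess", counts)
    return store


@_stage("extract")
def extract_stage(config: RunConfig, out_dir: Path) -> Path:
    store = out_dir / "epochs.tsv.gz"
    if not store.exists():
        raise FileNotFoundError(f"epoch store not found: {store}")
    epochs, channel_labels = eio.read_epoch_store(store)
    tensor = extract_marker_tensor(
        epochs,
        channel_labels,
        wavelet_spec=config.wavelet,
        band_scheme=config.bands,
        entropy_params=config.entropy,
        markers=config.markers,
    )
    path = out_dir / "markers.tsv.gz"
    eio.write_tensor_tsv(tensor, path)
    _write_manifest(out_dir, "extract", {
        "epochs": len(epochs),
        "values": int(len(tensor)),
        "missing": int(tensor["missing"].sum()),
    })
    return path


@_stage("evaluate")
def evaluate_stage(config: RunConfig, out_dir: Path) -> Path:
    cohort = eio.read_cohort_tsv(out_dir / "cohort.tsv")
    tensor = eio.read_tensor_tsv(out_dir / "markers.tsv.gz")
    features = tensor_to_features(tensor)
    ev = config.evaluation
    results: dict = {"outcome": ev.outcome, "seed": config.seed, "models": {}}
    train_cohort = cohort[cohort["cohort_split"] == "train"]
    test_cohort = cohort[cohort["cohort_split"] == "test"]
    train_feats = features[
        features.index.get_level_values("eeg_id").isin(train_cohort["eeg_id"])
    ]
    flags = None
    if ev.variant == "two-step-ied":
        flags = pd.Series(
            (cohort["ied_status"] == "present").to_numpy(),
            index=cohort["eeg_id"].to_numpy(),
        )
    elif ev.variant == "two-step-lesion":
        flags = pd.Series(
            cohort["focal_lesion"].to_numpy(),
            index=cohort["eeg_id"].to_numpy(),
        )
    for algorithm in ev.algorithms:
        spec = ModelSpec(algorithm=algorithm)
        fm_train = build_feature_matrix(train_feats, cohort, ev.outcome)
        res, preds = nested_cv_evaluate(
            fm_train,
            spec,
            inner_k=ev.inner_k,
            outer_k=ev.outer_k,
            q=ev.quantile,
            seed=config.seed,
            variant=ev.variant,
            flags=flags,
        )
        entry = {
            "nested_cv": {
                "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "ci_method": res.ci_method, "per_fold_aucs": res.per_fold_aucs,
                "p_vs_chance": res.p_vs_chance, "n_eegs": res.n_eegs,
            }
        }
        eio.write_predictions_tsv(
            preds.per_eeg, out_dir / f"predictions_{algorithm}.tsv"
        )
        if len(test_cohort) > 0:
            test_feats = features[
                features.index.get_level_values("eeg_id").isin(test_cohort["eeg_id"])
            ]
            fm_test = build_feature_matrix(test_feats, cohort, ev.outcome)
            hres, hpreds, metrics = holdout_evaluate(
                fm_train, fm_test, spec,
                q=ev.quantile, inner_k=ev.inner_k, seed=config.seed,
            )
            entry["holdout"] = {
                "auc": hres.auc, "ci_low": hres.ci_low, "ci_high": hres.ci_high,
                "ci_method": hres.ci_method, "n_eegs": hres.n_eegs,
                "binary_metrics": {
                    k: v for k, v in metrics.items() if not k.endswith("_ci")
                },
            }
            eio.write_predictions_tsv(
                hpreds.per_eeg, out_dir / f"holdout_predictions_{algorithm}.tsv"
            )
        results["models"][algorithm] = entry
    path = out_dir / "evaluation.json"
    path.write_text(json.dumps(results, indent=2))
    _write_manifest(out_dir, "evaluate", {
        "n_train_eegs": int(len(train_cohort)),
        "n_test_eegs": int(len(test_cohort)),
        "algorithms": list(ev.algorithms),
    })
    return path


@_stage("posthoc")
def posthoc_stage(config: RunConfig, out_dir: Path) -> Path:
    cohort = eio.read_cohort_tsv(out_dir / "cohort.tsv")
    ev = config.evaluation
    algorithm = ev.algorithms[0]
    preds_path = out_dir / f"predictions_{algorithm}.tsv"
    if not preds_path.exists():
        raise FileNotFoundError(f"predictions not found: {preds_path}")
    per_eeg = pd.read_csv(preds_path, sep="\t")
    from .evaluation import PredictionSet

    predset = PredictionSet(
        epoch_scores=per_eeg, per_eeg=per_eeg, quantile=ev.quantile
    )
    report: dict = {"algorithm": algorithm, "subgroups": {}, "survival": {}}
    for variable in SUBGROUP_VARIABLES:
        table = subgroup_auc(predset, cohort, SubgroupSpec(variable))
        report["subgroups"][variable] = table.to_dict(orient="records")

    merged = per_eeg.merge(cohort, on="eeg_id", suffixes=("", "_cohort"))
    high = dichotomize_risk(merged["score"].to_numpy())
    merged["risk_group"] = np.where(high, "high", "low")
    cox = fit_cox(
        merged["time_to_event_weeks"].to_numpy(),
        merged["event_observed"].to_numpy(),
        pd.DataFrame(
            {
                "risk_group": high.astype(float),
                "age": merged["age"].to_numpy(),
                "sex": merged["sex"].to_numpy(),
                "asm_count": merged["asm_count"].to_numpy(dtype=float),
            }
        ),
    )
    km = kaplan_meier(
        merged["time_to_event_weeks"].to_numpy(),
        merged["event_observed"].to_numpy(),
        merged["risk_group"].to_numpy(),
    )
    report["survival"] = {
        "hazard_ratios": cox.hazard_ratios.to_dict(orient="records"),
        "survival_52w": km.survival_52w,
        "logrank_stat": km.logrank_stat,
        "logrank_p": km.logrank_p,
    }
    for name, curve in km.km_curves.items():
        curve.to_csv(out_dir / f"km_curve_{name}.tsv", sep="\t", index=False)
    path = out_dir / "posthoc.json"
    path.write_text(json.dumps(report, indent=2))
    _write_manifest(out_dir, "posthoc", {"n_eegs": int(len(per_eeg))})
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns the paths of the result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.simulation.seed = config.seed
    paths = {
        "cohort": simulate_stage(config, out_dir),
        "epochs": preprocess_stage(config, out_dir),
        "markers": extract_stage(config, out_dir),
        "evaluation": evaluate_stage(config, out_dir),
        "posthoc": posthoc_stage(config, out_dir),
    }
    return {k: str(v) for k, v in paths.items()}
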