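"""Subgroup AUCs, marker comparison plumbing, survival models, metrics."""

import numpy as np
import pandas as pd
import pytest

from eegprognosis.evaluation import PredictionSet, auc_ci_ledell
from eegprognosis.posthoc import (
    SubgroupSpec,
    binary_metrics,
    dichotomize_risk,
    fit_cox,
    fold_manifest_hash,
    kaplan_meier,
    subgroup_auc,
)


def _prediction_set(rng, n=40):
    labels = rng.integers(0, 2, n)
    scores = np.clip(0.4 + 0.3 * labels + 0.15 * rng.standard_normal(n), 0, 1)
    per_eeg = pd.DataFrame(
        {
            "eeg_id": [f"E{i:03d}" for i in range(n)],
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "fold": np.arange(n) % 5,
            "score": scores,
            "label": labels,
        }
    )
    return PredictionSet(epoch_scores=per_eeg, per_eeg=per_eeg, quantile=0.5)


def _cohort_for(preds, rng):
    n = len(preds.per_eeg)
    return pd.DataFrame(
        {
            "eeg_id": preds.per_eeg["eeg_id"],
            "patient_id": preds.per_eeg["patient_id"],
            "age": rng.uniform(20, 80, n),
            "sex": rng.choice(["woman", "man"], n),
            "asm_count": rng.poisson(1, n),
            "ied_status": rng.choice(["absent", "present"], n),
            "focal_lesion": rng.uniform(size=n) < 0.4,
            "slowing": rng.uniform(size=n) < 0.3,
            "epilepsy_type": rng.choice(["focal", "none"], n),
        }
    )


class TestSubgroupAUC:
    def test_single_stratum_equals_overall(self, rng):
        preds = _prediction_set(rng)
        cohort = _cohort_for(preds, rng)
        cohort["sex"] = "woman"
        table = subgroup_auc(preds, cohort, SubgroupSpec("sex"))
        assert len(table) == 1
        overall = auc_ci_ledell(
            preds.per_eeg["score"].to_numpy(),
            preds.per_eeg["label"].to_numpy(),
            preds.per_eeg["fold"].to_numpy(),
        )
        assert table.iloc[0]["auc"] == pytest.approx(overall.auc)

    def test_small_stratum_not_estimable(self, rng):
        preds = _prediction_set(rng, n=12)
        cohort = _cohort_for(preds, rng)
        cohort["focal_lesion"] = [True] * 2 + [False] * 10
        table = subgroup_auc(preds, cohort, SubgroupSpec("focal_lesion"))
        flagged = table.set_index("stratum")
        assert not flagged.loc["True", "estimable"]

    def test_unknown_variable_errors(self):
        with pytest.raises(ValueError, match="unknown subgroup"):
            SubgroupSpec("handedness")


class TestDichotomize:
    def test_mean_split_and_tie_rule(self):
        assert dichotomize_risk(np.array([0.2, 0.8])).tolist() == [False, True]
        assert not dichotomize_risk(np.full(5, 0.5)).any()

    def test_median_option_and_guard(self):
        groups = dichotomize_risk(np.array([0.1, 0.2, 0.9]), method="median")
        assert groups.tolist() == [False, False, True]
        with pytest.raises(ValueError, match="2 EEGs"):
            dichotomize_risk(np.array([0.5]))


class TestBinaryMetrics:
    def test_perfect_scores(self):
        m = binary_metrics(np.array([0.9, 0.9, 0.1, 0.1]), np.array([1, 1, 0, 0]))
        assert m["sensitivity"] == m["specificity"] == m["ppv"] == m["npv"] == 1.0

    def test_confusion_arithmetic_and_ppv_identity(self):
        scores = np.concatenate(
            [np.full(10, 0.9), np.full(5, 0.1), np.full(3, 0.9), np.full(12, 0.1)]
        )
        labels = np.array([1] * 15 + [0] * 15)
        m = binary_metrics(scores, labels)
        assert (m["tp"], m["fn"], m["fp"], m["tn"]) == (10, 5, 3, 12)
        assert m["sensitivity"] == pytest.approx(10 / 15)
        assert m["specificity"] == pytest.approx(12 / 15)
        assert m["ppv"] == pytest.approx(10 / 13)
        assert m["npv"] == pytest.approx(12 / 17)
        prev = 15 / 30
        ppv_identity = (m["sensitivity"] * prev) / (
            m["sensitivity"] * prev + (1 - m["specificity"]) * (1 - prev)
        )
        assert m["ppv"] == pytest.approx(ppv_identity)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            binary_metrics(np.array([0.1, 0.9]), np.array([1, 1]))


class TestKaplanMeier:
    def test_closed_form_steps_without_censoring(self):
        res = kaplan_meier(
            np.array([1.0, 2.0, 3.0]), np.array([True] * 3), np.zeros(3, int)
        )
        curve = res.km_curves["0"]
        surv = curve.set_index("time_weeks")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_survival(self):
        res = kaplan_meier(
            np.array([10.0, 20.0]), np.array([False, False]), np.zeros(2, int)
        )
        assert (res.km_curves["0"]["survival"] == 1.0).all()

    def test_logrank_separates_groups(self):
        rng = np.random.default_rng(0)
        t0 = rng.exponential(50, 300)
        t1 = rng.exponential(15, 300)
        times = np.concatenate([t0, t1])
        events = np.ones(600, bool)
        groups = np.array([0] * 300 + [1] * 300)
        res = kaplan_meier(times, events, groups)
        assert res.logrank_p < 1e-6


class TestCox:
    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(3)
        n = 800
        group = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * group)))
        cens = rng.uniform(26, 156, n)
        res = fit_cox(
            np.minimum(t, cens),
            t <= cens,
            pd.DataFrame({"risk_group": group}),
        )
        row = res.hazard_ratios.set_index("covariate").loc["risk_group"]
        assert row["log_hr"] == pytest.approx(np.log(2.0), abs=0.3)
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]

    def test_zero_events_and_negative_times_error(self):
        cov = pd.DataFrame({"risk_group": [0.0, 1.0]})
        with pytest.raises(ValueError, match="events"):
            fit_cox(np.array([5.0, 6.0]), np.array([False, False]), cov)
        with pytest.raises(ValueError, match="negative"):
            fit_cox(np.array([-1.0, 6.0]), np.array([True, False]), cov)


def test_fold_manifest_hash_is_order_invariant():
    pats = np.array(["a", "b", "c"])
    folds = np.array([0, 1, 2])
    h1 = fold_manifest_hash(pats, folds)
    h2 = fold_manifest_hash(pats[::-1], folds[::-1])
    assert h1 == h2
    assert h1 != fold_manifest_hash(pats, np.array([0, 1, 1]))


class TestNullLogrankUniformity:
    def test_logrank_p_uniform_under_null(self):
        """Two groups from the same exponential law: logrank p-values over
        200 replicates should be indistinguishable from uniform (KS test)."""
        from scipy import stats as sstats

        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            t = rng.exponential(40.0, 80)
            cens = rng.uniform(26, 156, 80)
            time = np.minimum(t, cens)
            event = t <= cens
            group = np.array([0] * 40 + [1] * 40)
            res = kaplan_meier(time, event, group)
            pvals.append(res.logrank_p)
        ks = sstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSubgroupHeterogeneity:
    def test_injected_ordering_recovered(self, rng):
        """Scores informative only for lesion-negative EEGs: that stratum's
        AUC should exceed the lesion-positive stratum's in most seeds."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 60
            lesion = r.uniform(size=n) < 0.5
            labels = r.integers(0, 2, n)
            scores = np.where(
                lesion,
                r.uniform(size=n),  # uninformative stratum
                np.clip(0.35 + 0.3 * labels + 0.12 * r.standard_normal(n), 0, 1),
            )
            per_eeg = pd.DataFrame(
                {
                    "eeg_id": [f"E{i:03d}" for i in range(n)],
                    "patient_id": [f"P{i:03d}" for i in range(n)],
                    "fold": np.arange(n) % 5,
                    "score": scores,
                    "label": labels,
                }
            )
            preds = PredictionSet(epoch_scores=per_eeg, per_eeg=per_eeg, quantile=0.5)
            cohort = pd.DataFrame(
                {"eeg_id": per_eeg["eeg_id"], "focal_lesion": lesion}
            )
            table = subgroup_auc(preds, cohort, SubgroupSpec("focal_lesion")).set_index(
                "stratum"
            )
            if table.loc["False", "auc"] > table.loc["True", "auc"] + 0.1:
                wins += 1
        assert wins >= 8


class TestCompareMarkers:
    def test_union_and_shared_manifest(self, rng):
        """Per-marker runs share one fold manifest; the union of markers is
        not much worse than the best single marker on identical splits."""
        from eegprognosis.config import ModelSpec
        from eegprognosis.evaluation import FeatureMatrix
        from eegprognosis.posthoc import compare_markers

        n_patients, epochs_per = 24, 3
        labels_by_patient = rng.integers(0, 2, n_patients)
        labels_by_patient[:4] = 1
        labels_by_patient[4:8] = 0
        rows, pats, eegs, labels = [], [], [], []
        for p in range(n_patients):
            for e in range(epochs_per):
                x = rng.standard_normal(6)
                x[0] += 2.0 * labels_by_patient[p]  # only "alpha" informative
                rows.append(x)
                pats.append(f"P{p:03d}")
                eegs.append(f"E{p:03d}")
                labels.append(labels_by_patient[p])
        X = pd.DataFrame(rows, columns=[f"f{i}" for i in range(6)])
        base = dict(
            eeg_ids=np.array(eegs), patient_ids=np.array(pats),
            labels=np.array(labels),
        )
        by_marker = {
            "alpha": FeatureMatrix(X=X[["f0", "f1"]], **base),
            "beta": FeatureMatrix(X=X[["f2", "f3"]], **base),
            "gamma": FeatureMatrix(X=X[["f4", "f5"]], **base),
        }
        spec = ModelSpec(
            "glm_logistic_l1l2", grid=[{"penalty": "l2", "C": 1.0}],
            fs_c_grid=(0.1,),
        )
        table = compare_markers(
            by_marker, spec, inner_k=3, outer_k=4, seed=0, include_union=True
        )
        assert table["fold_manifest"].nunique() == 1
        assert table.iloc[0]["marker"] in ("alpha", "combined")
        best_single = table[table["marker"] != "combined"]["auc"].max()
        combined = table.set_index("marker").loc["combined", "auc"]
        assert combined >= best_single - 0.05
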