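"""Grouped folds, AUC inference, aggregation, variants, nested CV."""

import numpy as np
import pandas as pd
import pytest

from eegprognosis.config import ModelSpec
from eegprognosis.evaluation import (
    AgeInteractionTransform,
    FeatureMatrix,
    aggregate_epoch_predictions,
    auc_ci_delong,
    auc_ci_ledell,
    build_feature_matrix,
    feature_select_l1svm,
    grouped_folds,
    holdout_evaluate,
    mann_whitney_auc,
    nested_cv_evaluate,
    outcome_labels,
    two_step_classify,
)
from eegprognosis.validation import pair_counting_auc

TINY_SPEC = ModelSpec(
    "glm_logistic_l1l2", grid=[{"penalty": "l2", "C": 1.0}], fs_c_grid=(0.1,)
)


def _feature_cohort(rng, n_patients=20, epochs_per=3, effect=2.0, n_features=10):
    """Patient-grouped epoch features with a class shift on the first column."""
    labels_by_patient = (rng.uniform(size=n_patients) < 0.5).astype(int)
    if labels_by_patient.sum() in (0, n_patients):
        labels_by_patient[0] = 1 - labels_by_patient[0]
    rows, eegs, pats, labels = [], [], [], []
    for p in range(n_patients):
        for e in range(epochs_per):
            x = rng.standard_normal(n_features)
            x[0] += effect * labels_by_patient[p]
            rows.append(x)
            eegs.append(f"E{p:03d}")
            pats.append(f"P{p:03d}")
            labels.append(labels_by_patient[p])
    return FeatureMatrix(
        X=pd.DataFrame(rows),
        eeg_ids=np.array(eegs),
        patient_ids=np.array(pats),
        labels=np.array(labels),
        age=np.full(len(rows), 50.0),
    )


class TestGroupedFolds:
    def test_balanced_disjoint_assignment(self):
        patients = np.repeat([f"P{i}" for i in range(10)], 4)
        folds = grouped_folds(patients, 5, seed=1)
        df = pd.DataFrame({"p": patients, "f": folds})
        assert (df.groupby("p")["f"].nunique() == 1).all()
        per_fold = df.groupby("f")["p"].nunique()
        assert sorted(per_fold) == [2, 2, 2, 2, 2]

    def test_deterministic_and_guarded(self):
        patients = np.array(["a", "b", "c", "b", "a"])
        assert np.array_equal(
            grouped_folds(patients, 3, seed=7), grouped_folds(patients, 3, seed=7)
        )
        with pytest.raises(ValueError, match="distinct patients"):
            grouped_folds(patients, 4, seed=0)


class TestAggregation:
    def test_median_and_quantile_convention(self):
        df = pd.DataFrame({"eeg_id": ["a"] * 3, "score": [0.2, 0.8, 0.4]})
        assert aggregate_epoch_predictions(df, 0.5)["a"] == pytest.approx(0.4)
        ten = pd.DataFrame(
            {"eeg_id": ["b"] * 10, "score": np.arange(0.1, 1.05, 0.1)}
        )
        assert aggregate_epoch_predictions(ten, 0.9)["b"] == pytest.approx(0.91)

    def test_single_epoch_any_quantile(self):
        df = pd.DataFrame({"eeg_id": ["a"], "score": [0.77]})
        for q in (0.1, 0.5, 0.9):
            assert aggregate_epoch_predictions(df, q)["a"] == pytest.approx(0.77)

    def test_quantile_bounds(self):
        df = pd.DataFrame({"eeg_id": ["a"], "score": [0.5]})
        with pytest.raises(ValueError, match="quantile"):
            aggregate_epoch_predictions(df, 0.95)


class TestDeLong:
    def test_trivial_instances(self):
        res = auc_ci_delong(np.array([0.8, 0.9, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert res.auc == 1.0
        assert res.ci_high == 1.0
        assert auc_ci_delong(np.full(10, 0.5), np.array([1] * 4 + [0] * 6)).auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(12):
            n = int(rng.integers(10, 51))
            y = np.zeros(n, int)
            y[: n // 3 + 1] = 1
            rng.shuffle(y)
            s = np.round(rng.uniform(size=n), 1)
            assert auc_ci_delong(s, y).auc == pytest.approx(
                pair_counting_auc(s, y), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_ci_delong(np.array([0.1, 0.2]), np.array([1, 1]))


class TestLeDell:
    def test_point_estimate_is_fold_mean(self, rng):
        scores, labels, folds = [], [], []
        for f in range(4):
            s = np.array([0.9, 0.8, 0.7, 0.2, 0.3, 0.1])
            y = np.array([1, 1, 1, 0, 0, 0])
            scores.append(s), labels.append(y), folds.append(np.full(6, f))
        res = auc_ci_ledell(
            np.concatenate(scores), np.concatenate(labels), np.concatenate(folds)
        )
        assert res.auc == 1.0
        assert res.ci_high == 1.0
        assert res.per_fold_aucs == [1.0] * 4

    def test_single_class_fold_excluded(self):
        scores = np.array([0.9, 0.1, 0.8, 0.2, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0, 1, 1])
        folds = np.array([0, 0, 1, 1, 2, 2])  # fold 2 all-positive
        res = auc_ci_ledell(scores, labels, folds)
        assert len(res.per_fold_aucs) == 2
        assert res.auc == 1.0

    def test_mann_whitney_tie_convention(self):
        assert mann_whitney_auc(
            np.array([1.0, 1.0, 0.0]), np.array([1, 0, 0])
        ) == pytest.approx(0.75)


class TestVariants:
    def test_two_step_override(self):
        flags = np.array([True, False, False])
        scores = np.array([0.1, 0.6, 0.3])
        assert np.allclose(two_step_classify(flags, scores), [1.0, 0.6, 0.3])
        assert np.allclose(
            two_step_classify(np.zeros(3, bool), scores), scores
        )

    def test_two_step_improves_over_parts(self, rng):
        labels = (rng.uniform(size=600) < 0.3).astype(int)
        flags = (labels == 1) & (rng.uniform(size=600) < 0.5)
        model = 0.4 + 0.2 * labels + 0.1 * rng.standard_normal(600)
        combined = two_step_classify(flags, model)
        auc_c = mann_whitney_auc(combined, labels)
        assert auc_c >= mann_whitney_auc(flags.astype(float), labels)

    def test_age_interactions_shape_and_statistics(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 4)))
        age = np.array([40.0, 50.0, 60.0, 45.0, 55.0, 50.0])
        tf = AgeInteractionTransform().fit(age)
        out = tf.transform(X, age)
        assert out.shape == (6, 2 * 4 + 1)
        mean_row = tf.transform(X.iloc[:1], np.array([tf.mean_]))
        assert np.allclose(mean_row.iloc[0, 4:], 0.0)
        # held-out rows use the training statistics, not their own
        held = tf.transform(X.iloc[:2], np.array([100.0, 100.0]))
        assert np.allclose(held["age"], (100.0 - tf.mean_) / tf.sd_)
        with pytest.raises(ValueError, match="missing age"):
            tf.transform(X, np.array([np.nan] * 6))


class TestFeatureSelection:
    def test_informative_column_retained(self):
        kept = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((400, 51))
            y = rng.integers(0, 2, 400)
            X[:, 0] += 2.0 * y
            X = (X - X.mean(0)) / X.std(0)
            mask = feature_select_l1svm(X, y, c=0.05, seed=seed)
            kept += bool(mask[0])
        assert kept >= 9

    def test_empty_selection_falls_back_to_all(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.integers(0, 2, 40)
        mask = feature_select_l1svm(X, y, c=1e-6)
        assert mask.all()

    def test_duplicated_informative_column(self, rng):
        y = rng.integers(0, 2, 300)
        a = rng.standard_normal(300) + 2.0 * y
        X = np.column_stack([a, a, rng.standard_normal((300, 20))])
        mask = feature_select_l1svm((X - X.mean(0)) / X.std(0), y, c=0.1)
        assert mask[0] or mask[1]

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            feature_select_l1svm(rng.standard_normal((10, 3)), np.ones(10))


class TestNestedCV:
    def test_strong_effect_detected(self, rng):
        fm = _feature_cohort(rng, effect=2.5)
        res, preds = nested_cv_evaluate(fm, TINY_SPEC, inner_k=3, outer_k=4, seed=0)
        assert res.auc > 0.85
        assert res.ci_low <= res.auc <= res.ci_high
        # per-EEG aggregation: exactly the quantile of that EEG's epochs
        one = preds.epoch_scores[preds.epoch_scores["eeg_id"] == "E000"]
        agg = preds.per_eeg.set_index("eeg_id").loc["E000", "score"]
        assert agg == pytest.approx(np.quantile(one["score"], 0.5))

    def test_patients_never_straddle_folds(self, rng):
        fm = _feature_cohort(rng)
        _, preds = nested_cv_evaluate(fm, TINY_SPEC, inner_k=3, outer_k=4, seed=0)
        spread = preds.epoch_scores.groupby("patient_id")["fold"].nunique()
        assert (spread == 1).all()

    def test_injected_fold_ids_respected(self, rng):
        fm = _feature_cohort(rng)
        folds = grouped_folds(fm.patient_ids, 4, seed=99)
        _, preds = nested_cv_evaluate(fm, TINY_SPEC, inner_k=3, fold_ids=folds)
        expected = pd.Series(folds, index=fm.eeg_ids).groupby(level=0).first()
        observed = preds.per_eeg.set_index("eeg_id")["fold"]
        assert (observed == expected.loc[observed.index]).all()

    def test_single_class_cohort_errors(self, rng):
        fm = _feature_cohort(rng)
        fm.labels[:] = 1
        with pytest.raises(ValueError, match="outer folds"):
            nested_cv_evaluate(fm, TINY_SPEC, inner_k=3, outer_k=4, seed=0)


class TestHoldout:
    def test_patient_overlap_rejected(self, rng):
        fm = _feature_cohort(rng)
        with pytest.raises(ValueError, match="both splits"):
            holdout_evaluate(fm, fm, TINY_SPEC)

    def test_split_evaluation_and_binary_metrics(self, rng):
        fm = _feature_cohort(rng, n_patients=30, effect=2.5)
        train_mask = np.isin(fm.patient_ids, [f"P{i:03d}" for i in range(20)])
        res, preds, metrics = holdout_evaluate(
            fm.subset(train_mask), fm.subset(~train_mask), TINY_SPEC, inner_k=3
        )
        assert res.ci_method == "delong"
        assert res.auc > 0.8
        assert set(metrics) >= {"sensitivity", "specificity", "ppv", "npv"}

    def test_binary_comparator_flags_through_delong(self):
        """IED presence scored {1, 0} runs through the same AUC machinery."""
        flags = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        labels = np.array([1, 1, 0, 0, 0, 1])
        res = auc_ci_delong(flags, labels)
        assert 0.0 <= res.auc <= 1.0


class TestOutcomeLabels:
    def test_three_outcomes_derived(self, short_sim_config):
        from eegprognosis.synthetic import simulate_cohort_table

        cohort = simulate_cohort_table(short_sim_config)
        rec = outcome_labels(cohort, "recurrence_1y")
        diag = outcome_labels(cohort, "epilepsy_diagnosis")
        active = outcome_labels(cohort, "active_epilepsy")
        assert (active <= diag).all()  # active epilepsy implies a diagnosis
        assert ((~rec) | (cohort.set_index("eeg_id")["event_observed"])).all()
        with pytest.raises(ValueError, match="unknown outcome"):
            outcome_labels(cohort, "nope")

    def test_build_feature_matrix_joins_cohort(self, rng, short_sim_config):
        from eegprognosis.synthetic import simulate_cohort_table

        cohort = simulate_cohort_table(short_sim_config)
        idx = pd.MultiIndex.from_product(
            [cohort["eeg_id"], [0, 1]], names=["eeg_id", "epoch_index"]
        )
        feats = pd.DataFrame(
            rng.standard_normal((len(idx), 3)), index=idx, columns=list("abc")
        )
        fm = build_feature_matrix(feats, cohort)
        assert fm.n_epochs == len(idx)
        assert set(fm.patient_ids) == set(cohort["patient_id"])


class TestAggregationInvariance:
    def test_constant_epoch_scores_aggregate_to_constant(self):
        df = pd.DataFrame({"eeg_id": ["a"] * 7, "score": [0.9] * 7})
        for q in (0.1, 0.3, 0.5, 0.7, 0.9):
            assert aggregate_epoch_predictions(df, q)["a"] == pytest.approx(0.9)


class TestMonotoneDataBenefit:
    def test_doubling_cohort_does_not_hurt(self, rng):
        """Mean nested-CV AUC with 2n patients is no worse than with n
        beyond two standard errors (sanity property of the pipeline)."""
        small, large = [], []
        for seed in range(6):
            r = np.random.default_rng(seed)
            fm_s = _feature_cohort(r, n_patients=16, effect=1.0)
            fm_l = _feature_cohort(r, n_patients=32, effect=1.0)
            res_s, _ = nested_cv_evaluate(fm_s, TINY_SPEC, inner_k=3, outer_k=4, seed=seed)
            res_l, _ = nested_cv_evaluate(fm_l, TINY_SPEC, inner_k=3, outer_k=4, seed=seed)
            small.append(res_s.auc)
            large.append(res_l.auc)
        small, large = np.array(small), np.array(large)
        diff = large.mean() - small.mean()
        se = np.sqrt(small.var(ddof=1) / 6 + large.var(ddof=1) / 6)
        assert diff >= -2 * se


class TestNestedCVVariants:
    def test_age_interaction_variant_runs(self, rng):
        fm = _feature_cohort(rng, effect=2.0)
        res, _ = nested_cv_evaluate(
            fm, TINY_SPEC, inner_k=3, outer_k=4, seed=0, variant="age-interaction"
        )
        assert 0.0 <= res.auc <= 1.0

    def test_two_step_variant_overrides_flagged_eegs(self, rng):
        fm = _feature_cohort(rng, effect=1.0)
        flagged_ids = pd.unique(fm.eeg_ids)[:4]
        flags = pd.Series(
            np.isin(pd.unique(fm.eeg_ids), flagged_ids), index=pd.unique(fm.eeg_ids)
        )
        _, preds = nested_cv_evaluate(
            fm, TINY_SPEC, inner_k=3, outer_k=4, seed=0,
            variant="two-step-ied", flags=flags,
        )
        scored = preds.per_eeg.set_index("eeg_id")
        assert (scored.loc[flagged_ids, "score"] == 1.0).all()
        with pytest.raises(ValueError, match="flags"):
            nested_cv_evaluate(fm, TINY_SPEC, inner_k=3, variant="two-step-ied")
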