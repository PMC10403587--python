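"""Model/Results interface over the evaluation machinery.

`SeizureRecurrenceModel` is built from an epoch-level feature matrix and a
cohort table; `fit()` runs the patient-grouped nested cross-validation (or
the temporally shifted holdout protocol) and returns a results object
carrying the AUC estimate, its confidence interval, per-fold detail, the
prediction set, and post-hoc helpers (subgroup AUCs, dichotomized-risk
survival analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ModelSpec
from .evaluation import (
    EvaluationResult,
    FeatureMatrix,
    PredictionSet,
    build_feature_matrix,
    holdout_evaluate,
    nested_cv_evaluate,
)


class SeizureRecurrenceModel:
    """One-year seizure-recurrence classifier evaluated at the EEG level.

    Parameters
    ----------
    features
        Epoch-level feature table indexed by (eeg_id, epoch_index), e.g.
        from :func:`eegprognosis.markers.tensor_to_features`.
    cohort
        Clinical table with one row per EEG (patient_id, outcome fields,
        covariates, cohort_split).
    outcome
        ``recurrence_1y`` (default), ``epilepsy_diagnosis`` or
        ``active_epilepsy``.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        cohort: pd.DataFrame,
        outcome: str = "recurrence_1y",
        model_spec: Optional[ModelSpec] = None,
        quantile: float = 0.5,
        variant: str = "plain",
    ) -> None:
        self.features = features
        self.cohort = cohort.reset_index(drop=True)
        self.outcome = outcome
        self.model_spec = model_spec or ModelSpec()
        self.quantile = quantile
        self.variant = variant

    @classmethod
    def from_marker_tensor(cls, tensor: pd.DataFrame, cohort: pd.DataFrame, **kwargs):
        from .markers import tensor_to_features

        return cls(tensor_to_features(tensor), cohort, **kwargs)

    # -- helpers ---------------------------------------------------------

    def _matrix(self, split: Optional[str]) -> FeatureMatrix:
        feats = self.features
        if split is not None:
            keep = self.cohort.loc[self.cohort["cohort_split"] == split, "eeg_id"]
            feats = feats[feats.index.get_level_values("eeg_id").isin(keep)]
            if feats.empty:
                raise ValueError(f"no epochs in cohort split {split!r}")
        return build_feature_matrix(feats, self.cohort, self.outcome)

    def _flags(self) -> Optional[pd.Series]:
        if self.variant == "two-step-ied":
            vals = (self.cohort["ied_status"] == "present").to_numpy()
        elif self.variant == "two-step-lesion":
            vals = self.cohort["focal_lesion"].to_numpy()
        else:
            return None
        return pd.Series(vals, index=self.cohort["eeg_id"].to_numpy())

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        method: str = "nested_cv",
        outer_k: int = 5,
        inner_k: int = 10,
        seed: int = 0,
        fold_ids=None,
    ) -> "SeizureRecurrenceResults":
        """Evaluate the classifier; ``method`` is 'nested_cv' or 'holdout'."""
        if method == "nested_cv":
            fm = self._matrix("train" if "cohort_split" in self.cohort else None)
            result, preds = nested_cv_evaluate(
                fm,
                self.model_spec,
                inner_k=inner_k,
                outer_k=outer_k,
                q=self.quantile,
                seed=seed,
                fold_ids=fold_ids,
                variant=self.variant,
                flags=self._flags(),
            )
            return SeizureRecurrenceResults(self, method, result, preds, None)
        if method == "holdout":
            res, preds, metrics = holdout_evaluate(
                self._matrix("train"),
                self._matrix("test"),
                self.model_spec,
                q=self.quantile,
                inner_k=inner_k,
                seed=seed,
            )
            return SeizureRecurrenceResults(self, method, res, preds, metrics)
        raise ValueError("method must be 'nested_cv' or 'holdout'")


@dataclass
class SeizureRecurrenceResults:
    """Fitted evaluation: AUC, CI, prediction set, post-hoc accessors."""

    model: SeizureRecurrenceModel
    method: str
    evaluation: EvaluationResult
    predictions: PredictionSet
    binary_metrics: Optional[dict]

    @property
    def auc(self) -> float:
        return self.evaluation.auc

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.evaluation.ci_low, self.evaluation.ci_high)

    @property
    def pvalue(self) -> float:
        return self.evaluation.p_vs_chance

    def subgroup_auc(self, variable: str) -> pd.DataFrame:
        from .posthoc import SubgroupSpec, subgroup_auc

        return subgroup_auc(self.predictions, self.model.cohort, SubgroupSpec(variable))

    def survival_analysis(self, method: str = "mean"):
        """Cox model (risk group + age, sex, ASM count) and KM curves."""
        from .posthoc import dichotomize_risk, fit_cox, kaplan_meier

        merged = self.predictions.per_eeg.merge(self.model.cohort, on="eeg_id",
                                                suffixes=("", "_cohort"))
        high = dichotomize_risk(merged["score"].to_numpy(), method=method)
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
            np.where(high, "high", "low"),
        )
        return cox, km

    def plot_km(self, ax=None, method: str = "mean"):
        """Kaplan-Meier curves of the dichotomized predicted risk."""
        import matplotlib.pyplot as plt

        _, km = self.survival_analysis(method=method)
        if ax is None:
            _, ax = plt.subplots()
        for name, curve in km.km_curves.items():
            ax.step(curve["time_weeks"], curve["survival"], where="post",
                    label=f"{name} predicted risk")
            ax.fill_between(curve["time_weeks"], curve["ci_low"], curve["ci_high"],
                            step="post", alpha=0.2)
        ax.axvline(52.0, linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("weeks since EEG")
        ax.set_ylabel("seizure-free survival")
        ax.legend()
        return ax

    def summary(self) -> str:
        e = self.evaluation
        lines = [
            "Seizure-recurrence EEG classifier evaluation",
            "=" * 52,
            f"outcome:            {self.model.outcome}",
            f"algorithm:          {self.model.model_spec.algorithm}",
            f"variant:            {self.model.variant}",
            f"protocol:           {self.method}",
            f"aggregation q:      {self.model.quantile}",
            f"n EEGs:             {e.n_eegs}",
            f"ROC AUC:            {e.auc:.3f}",
            f"95% CI ({e.ci_method}): [{e.ci_low:.3f}, {e.ci_high:.3f}]",
            f"p vs chance:        {e.p_vs_chance:.4g}",
        ]
        if e.per_fold_aucs and self.method == "nested_cv":
            folds = ", ".join(f"{a:.3f}" for a in e.per_fold_aucs)
            lines.append(f"per-fold AUCs:      {folds}")
        if self.binary_metrics:
            m = self.binary_metrics
            lines.append(
                "binary @0.5:        "
                f"sens {m['sensitivity']:.2f}, spec {m['specificity']:.2f}, "
                f"PPV {m['ppv']:.2f}, NPV {m['npv']:.2f}"
            )
        return "\n".join(lines)
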