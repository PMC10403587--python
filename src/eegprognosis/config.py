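"""Parameter objects and configuration-file handling.

Every default that the analysis protocol fixes (filter cutoffs, epoch length,
band edges, wavelet family, entropy parameters, CV geometry) lives here so a
run is fully described by one :class:`RunConfig` plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


# ---------------------------------------------------------------------------
# Marker parameters
# ---------------------------------------------------------------------------

#: Ten analysis bands: low/high delta, theta, alpha, beta, gamma (Hz).
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("low_delta", 1.0, 2.0),
    ("high_delta", 2.0, 4.0),
    ("low_theta", 4.0, 6.0),
    ("high_theta", 6.0, 8.0),
    ("low_alpha", 8.0, 10.0),
    ("high_alpha", 10.0, 13.0),
    ("low_beta", 13.0, 20.0),
    ("high_beta", 20.0, 40.0),
    ("low_gamma", 40.0, 75.0),
    ("high_gamma", 75.0, 100.0),
)


@dataclass(frozen=True)
class BandScheme:
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ConfigError(f"band {name!r}: f_low must be < f_high")
            if lo < prev_high:
                raise ConfigError(f"band {name!r} overlaps the previous band")
            prev_high = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)


@dataclass(frozen=True)
class WaveletSpec:
    """Discrete wavelet decomposition of each epoch-channel series.

    With a 200 Hz sampling rate the six detail levels nominally cover
    100-50, 50-25, 25-12.5, 12.5-6.25, 6.25-3.125 and 3.125-1.56 Hz.
    """

    wavelet: str = "sym5"
    n_levels: int = 6

    def level_band(self, level: int, fs: float) -> tuple[float, float]:
        """Nominal frequency range of detail level ``level`` (1-based)."""
        return fs / 2 ** (level + 1), fs / 2 ** level


@dataclass(frozen=True)
class EntropyParams:
    """Shared parameters of the embedded/spectral complexity estimators.

    ``m``: embedding dimension; ``r``: tolerance as a fraction of the series
    SD; ``tau``: embedding delay in samples; ``n``: fuzzy membership exponent;
    ``k``: permutation (ordinal-pattern) order.
    """

    m: int = 3
    r: float = 0.25
    tau: int = 5
    n: float = 2.0
    k: int = 3

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("EntropyParams.m must be >= 1")
        if self.r <= 0:
            raise ConfigError("EntropyParams.r must be > 0")
        if self.tau < 1:
            raise ConfigError("EntropyParams.tau must be >= 1")
        if self.k < 2:
            raise ConfigError("EntropyParams.k must be >= 2")


# ---------------------------------------------------------------------------
# Synthetic-cohort configuration
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSchedule:
    """Technologist-annotation schedule emulated by the generator.

    Defaults mimic a rotating-montage routine EEG at reduced duration:
    montage changes every 150 s, one 90-s hyperventilation at t=60 s, photic
    trains at 4,6,...,22 Hz (10 s each), eye open/close events every 60 s.
    Set a field to ``None`` to drop that annotation family.
    """

    montage_interval_s: Optional[float] = 150.0
    hv_start_s: Optional[float] = 60.0
    hv_duration_s: float = 90.0
    photic_freqs_hz: Optional[tuple[float, ...]] = tuple(range(4, 24, 2))
    photic_train_s: float = 10.0
    photic_start_s: float = 160.0
    eye_interval_s: Optional[float] = 60.0

    def last_onset(self) -> float:
        onsets = [0.0]
        if self.hv_start_s is not None:
            onsets.append(self.hv_start_s + self.hv_duration_s + 120.0)
        if self.photic_freqs_hz:
            onsets.append(
                self.photic_start_s + len(self.photic_freqs_hz) * self.photic_train_s
            )
        return max(onsets)


@dataclass
class SurvivalParams:
    """Exponential time-to-recurrence model with censoring.

    Event time ~ Exp(lambda * exp(beta * risk)); follow-up drawn uniform on
    ``followup_range_weeks`` independently of the event process. When
    ``baseline_hazard_per_week`` is ``None`` the cohort generator calibrates
    it so the expected observed one-year recurrence equals the configured
    prevalence.
    """

    baseline_hazard_per_week: Optional[float] = None
    log_hazard_per_risk: float = 1.0
    followup_range_weeks: tuple[float, float] = (26.0, 156.0)

    def __post_init__(self) -> None:
        if (
            self.baseline_hazard_per_week is not None
            and self.baseline_hazard_per_week <= 0
        ):
            raise ConfigError("SurvivalParams.baseline_hazard_per_week must be > 0")
        lo, hi = self.followup_range_weeks
        if lo < 0 or hi < lo:
            raise ConfigError("SurvivalParams.followup_range_weeks must be 0 <= lo <= hi")


@dataclass
class SimulationConfig:
    """Ground-truth structure of one synthetic cohort.

    ``effect_sizes`` maps marker families to the shift applied to recordings
    of patients who recur: ``band_power`` in within-class SD units of log10
    alpha power, ``paf_hz`` in Hz on the alpha peak, ``entropy`` in SD units
    of the regularity contrast (positive = recurring patients more regular,
    i.e. lower entropy).
    """

    n_patients: int = 60
    prevalence_recurrence: float = 0.3
    duration_s: float = 300.0
    n_channels: int = 19
    sampling_rate: float = 200.0
    effect_sizes: dict = field(
        default_factory=lambda: {"band_power": 1.0, "paf_hz": -1.0, "entropy": 1.0}
    )
    ied_rate_positive: float = 1.0
    ied_rate_negative: float = 0.1
    artifact_rate: float = 0.5
    schedule: AnnotationSchedule = field(default_factory=AnnotationSchedule)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    test_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("SimulationConfig.n_patients must be >= 0")
        if not 0.0 <= self.prevalence_recurrence <= 1.0:
            raise ConfigError("SimulationConfig.prevalence_recurrence must be in [0, 1]")
        if not 0.0 <= self.test_fraction <= 1.0:
            raise ConfigError("SimulationConfig.test_fraction must be in [0, 1]")
        if self.duration_s <= 0:
            raise ConfigError("SimulationConfig.duration_s must be > 0")
        if self.sampling_rate <= 0:
            raise ConfigError("SimulationConfig.sampling_rate must be > 0")
        if self.n_channels < 2:
            raise ConfigError("SimulationConfig.n_channels must be >= 2")
        for fld in ("ied_rate_positive", "ied_rate_negative", "artifact_rate"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"SimulationConfig.{fld} must be >= 0")


# ---------------------------------------------------------------------------
# Evaluation configuration
# ---------------------------------------------------------------------------

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "glm_logistic_l1l2": [
        {"penalty": p, "C": c}
        for p in ("l1", "l2")
        for c in (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    ],
    "svm_rbf": [
        {"C": c, "gamma": g}
        for c in (1e-2, 1e-1, 1.0, 10.0, 100.0)
        for g in ("scale", 1e-3, 1e-2, 1e-1, 1.0)
    ],
    "random_forest": [
        {"n_estimators": 500, "max_depth": d, "min_samples_leaf": l}
        for d in (None, 8)
        for l in (1, 5)
    ],
    "gradient_boosted_trees": [
        {"n_estimators": 200, "learning_rate": lr, "num_leaves": nl}
        for lr in (0.05, 0.1)
        for nl in (15, 31)
    ],
}

ALGORITHMS = tuple(DEFAULT_GRIDS)


@dataclass
class ModelSpec:
    """One classification algorithm plus its hyperparameter grid and the
    L1-linear-SVM feature-selection C grid searched in the inner loop."""

    algorithm: str = "glm_logistic_l1l2"
    grid: list[dict] = None  # type: ignore[assignment]
    fs_c_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(
                f"ModelSpec.algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        if self.grid is None:
            self.grid = [dict(g) for g in DEFAULT_GRIDS[self.algorithm]]
        if not self.grid:
            raise ConfigError("ModelSpec.grid must be non-empty")
        if not self.fs_c_grid:
            raise ConfigError("ModelSpec.fs_c_grid must be non-empty")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class PreprocessingParams:
    hp_cutoff_hz: float = 0.75
    notch_hz: float = 60.0
    epoch_len_s: float = 10.0
    k_folds: int = 5
    n_threshold_candidates: int = 40
    max_bad_fraction: float = 0.3


@dataclass
class EvaluationParams:
    outer_k: int = 5
    inner_k: int = 10
    quantile: float = 0.5
    outcome: str = "recurrence_1y"
    algorithms: tuple[str, ...] = ("glm_logistic_l1l2",)
    variant: str = "plain"  # plain | age-interaction | two-step-ied | two-step-lesion
    bonferroni: bool = False


@dataclass
class RunConfig:
    """Everything a full pipeline run needs besides the input files."""

    out_dir: str = "eegprognosis_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    bands: BandScheme = field(default_factory=BandScheme)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)
    markers: Optional[tuple[str, ...]] = None  # None = all ten


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config, path: str | Path) -> None:
    """Serialize a config dataclass to a nested key/value YAML file."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def _build(cls, data: dict):
    kwargs = {}
    hints = {f.name: f for f in cls.__dataclass_fields__.values()}
    for key, value in data.items():
        if key not in hints:
            raise ConfigError(f"unknown field {key!r} for {cls.__name__}")
        kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from the YAML produced by :func:`save_config`."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return run_config_from_dict(data)


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    if "simulation" in data:
        data["simulation"] = simulation_config_from_dict(data["simulation"])
    if "preprocessing" in data:
        data["preprocessing"] = _build(PreprocessingParams, data["preprocessing"])
    if "entropy" in data:
        data["entropy"] = _build(EntropyParams, data["entropy"])
    if "bands" in data:
        data["bands"] = BandScheme(
            tuple(tuple(b) for b in data["bands"]["bands"])
        )
    if "wavelet" in data:
        data["wavelet"] = _build(WaveletSpec, data["wavelet"])
    if "evaluation" in data:
        ev = dict(data["evaluation"])
        if "algorithms" in ev:
            ev["algorithms"] = tuple(ev["algorithms"])
        data["evaluation"] = _build(EvaluationParams, ev)
    if data.get("markers") is not None:
        data["markers"] = tuple(data["markers"])
    return _build(RunConfig, data)


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    if "schedule" in data:
        sched = dict(data["schedule"])
        if sched.get("photic_freqs_hz") is not None:
            sched["photic_freqs_hz"] = tuple(sched["photic_freqs_hz"])
        data["schedule"] = _build(AnnotationSchedule, sched)
    if "survival" in data:
        surv = dict(data["survival"])
        if "followup_range_weeks" in surv:
            surv["followup_range_weeks"] = tuple(surv["followup_range_weeks"])
        data["survival"] = _build(SurvivalParams, surv)
    return _build(SimulationConfig, data)
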