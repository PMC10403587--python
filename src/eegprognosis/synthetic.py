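"""Synthetic routine-EEG cohorts with known ground-truth effect structure.

The generator stands in for a private clinical cohort: it produces annotated
multichannel recordings plus a clinical table with censored time-to-seizure
outcomes. The signal model is deliberately minimal yet exposes every marker
family the pipeline measures:

* pink (1/f) background noise mixed with a fixed low-order autoregressive
  share per channel,
* one shared alpha oscillator (Gaussian spectral bump, posterior-weighted)
  whose peak frequency and power shift with the patient's latent risk,
* a risk-scaled quasi-periodic fronto-temporal beta component whose
  near-periodicity carries the regularity (entropy) contrast between
  outcome classes, plus an optional power-neutral sliding-beta component
  ("bp_contrast") that moves band power without touching other markers,
* spike-and-slow-wave transients at a class-dependent rate and boxcar
  high-amplitude artifacts,
* a technologist-style annotation schedule (montage changes,
  hyperventilation, photic trains, eye events).

Units are microvolts throughout. Identical (config, seed) pairs reproduce
cohorts sample-for-sample.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps

from .config import ConfigError, SimulationConfig, SurvivalParams
from .containers import CHANNELS_1020, Annotation, Recording

#: log10 band-power shift of the alpha oscillator per unit of standardized
#: band-power effect (one within-class SD of epoch-level log10 alpha power).
ALPHA_LOG10_POWER_PER_UNIT = 0.2
#: Amplitude (in background-SD units) of the quasi-periodic beta component
#: per unit of standardized entropy effect; a dominant near-periodic
#: oscillation makes the beta-band wavelet coefficients more regular, which
#: lowers the ordinal/fuzzy entropies and the correlation dimension there.
ENTROPY_OSC_AMP_PER_UNIT = 0.7
_ENTROPY_OSC_FREQ_HZ = (17.0, 21.0)
#: The "bp_contrast" effect family adds a fixed-power beta source whose
#: center frequency slides from high beta (~21 Hz) toward low beta with
#: risk, staying inside wavelet level 3 (12.5-25 Hz). Band powers flip
#: between the low/high-beta bands while level energy and the unimodal
#: within-level spectral shape barely move, so the contrast is carried
#: almost exclusively by the band-power marker.
BP_CONTRAST_HZ_PER_UNIT = 1.8
_BP_CONTRAST_BASE_HZ = 21.0
_BP_CONTRAST_RANGE_HZ = (15.5, 23.0)
_BP_CONTRAST_BW_HZ = 2.0
_BP_CONTRAST_AMP = 6.0  # uV RMS at a weight-1.0 channel
#: Baseline AR-mixing weight and alpha parameters of the background model.
_BASE_AR_WEIGHT = 0.25
_BASE_ALPHA_FREQ = 10.5
_BASE_ALPHA_AMP = 8.0  # uV at a weight-1.0 (posterior) channel
_ALPHA_BANDWIDTH_HZ = 1.5
_BACKGROUND_SD = 10.0  # uV
_ALPHA_JITTER_LOG10 = 0.1  # per-recording lognormal amplitude jitter
_RISK_NOISE_SD = 0.25

#: Relative alpha-source weighting across the 19 channels (posterior dominant).
_ALPHA_WEIGHTS = {
    "O1": 1.0, "O2": 1.0, "P3": 0.85, "P4": 0.85, "Pz": 0.85, "P7": 0.7,
    "P8": 0.7, "C3": 0.5, "C4": 0.5, "Cz": 0.5, "T7": 0.4, "T8": 0.4,
    "F3": 0.3, "F4": 0.3, "Fz": 0.3, "F7": 0.25, "F8": 0.25,
    "Fp1": 0.2, "Fp2": 0.2,
}

#: Fronto-temporal weighting of the entropy-effect beta component; must be
#: spatially non-uniform or the average reference would cancel it.
_BETA_WEIGHTS = {
    "Fp1": 0.9, "Fp2": 0.9, "F3": 0.7, "F4": 0.7, "C3": 0.5, "C4": 0.5,
    "P3": 0.6, "P4": 0.6, "F7": 1.0, "F8": 1.0, "T7": 1.0, "T8": 1.0,
    "P7": 0.7, "P8": 0.7, "Fz": 0.4, "Cz": 0.3, "Pz": 0.4, "O1": 0.5,
    "O2": 0.5,
}

_NEIGHBORS = {  # 4-channel focal spread for spike-wave insertion
    name: nb for name, nb in {
        "Fp1": ("F3", "F7", "Fz"), "Fp2": ("F4", "F8", "Fz"),
        "F3": ("Fp1", "Fz", "C3"), "F4": ("Fp2", "Fz", "C4"),
        "C3": ("F3", "P3", "Cz"), "C4": ("F4", "P4", "Cz"),
        "P3": ("C3", "O1", "Pz"), "P4": ("C4", "O2", "Pz"),
        "O1": ("P3", "P7", "O2"), "O2": ("P4", "P8", "O1"),
        "F7": ("Fp1", "T7", "F3"), "F8": ("Fp2", "T8", "F4"),
        "T7": ("F7", "P7", "C3"), "T8": ("F8", "P8", "C4"),
        "P7": ("T7", "O1", "P3"), "P8": ("T8", "O2", "P4"),
        "Fz": ("F3", "F4", "Cz"), "Cz": ("C3", "C4", "Pz"),
        "Pz": ("P3", "P4", "Cz"),
    }.items()
}


# ---------------------------------------------------------------------------
# Elementary noise generators
# ---------------------------------------------------------------------------


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f-shaped Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def narrowband_noise(
    n: int, fs: float, f_peak: float, bandwidth: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD noise with a Gaussian spectral bump at ``f_peak`` Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    bump = np.exp(-0.5 * ((freqs - f_peak) / (bandwidth / 2.0)) ** 2)
    x = np.fft.irfft(spec * bump, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def ar1_noise(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD first-order autoregressive noise (smooth, predictable)."""
    x = sps.lfilter([1.0], [1.0, -phi], rng.standard_normal(n))
    return x / x.std()


def fractional_gaussian_noise(
    hurst: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact fractional Gaussian noise by Davies-Harte circulant embedding."""
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    k = np.arange(n + 1, dtype=np.float64)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma[:n], gamma[n:n + 1], gamma[1:n][::-1]])
    eigs = np.fft.fft(row).real
    eigs = np.maximum(eigs, 0.0)  # clip tiny negative rounding errors
    m = 2 * n
    # hermitian spectral draw so the inverse transform is exactly real
    w = np.zeros(m, dtype=np.complex128)
    w[0] = math.sqrt(eigs[0] / m) * rng.standard_normal()
    half = rng.standard_normal((2, n - 1))
    w[1:n] = np.sqrt(eigs[1:n] / (2.0 * m)) * (half[0] + 1j * half[1])
    w[n] = math.sqrt(eigs[n] / m) * rng.standard_normal()
    w[n + 1 :] = np.conj(w[1:n][::-1])
    return np.fft.fft(w).real[:n]


# ---------------------------------------------------------------------------
# Annotation schedule
# ---------------------------------------------------------------------------


def build_annotations(config: SimulationConfig) -> list[Annotation]:
    """Materialize the technologist annotation schedule for one recording."""
    sched = config.schedule
    dur = config.duration_s
    epoch_len = 10.0
    anns: list[Annotation] = []
    if sched.hv_start_s is not None:
        if sched.hv_start_s + sched.hv_duration_s > dur:
            raise ConfigError(
                "schedule.hv_start_s: hyperventilation window exceeds duration"
            )
        anns.append(Annotation(sched.hv_start_s, sched.hv_duration_s, "hyperventilation"))
    if sched.photic_freqs_hz:
        end = sched.photic_start_s + len(sched.photic_freqs_hz) * sched.photic_train_s
        if end > dur:
            raise ConfigError("schedule.photic_start_s: photic block exceeds duration")
        for i, f in enumerate(sched.photic_freqs_hz):
            anns.append(
                Annotation(
                    sched.photic_start_s + i * sched.photic_train_s,
                    sched.photic_train_s,
                    f"photic_{f:g}Hz",
                )
            )
    if sched.montage_interval_s:
        t = sched.montage_interval_s
        while t + epoch_len <= dur:
            anns.append(Annotation(t, 0.0, "montage_change"))
            t += sched.montage_interval_s
    if sched.eye_interval_s:
        t = sched.eye_interval_s
        toggle = True
        while t + epoch_len <= dur:
            anns.append(Annotation(t, 0.0, "eye_closed" if toggle else "eye_open"))
            toggle = not toggle
            t += sched.eye_interval_s
    anns.sort(key=lambda a: a.onset_s)
    return anns


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------


def simulate_recording(
    profile: pd.Series, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Recording:
    """Synthesize one annotated recording for a cohort row.

    The row's ``latent_risk`` (≈1 for recurring patients, ≈0 otherwise)
    scales the injected alpha-power, peak-frequency and regularity shifts
    through ``config.effect_sizes`` and sets the spike-wave insertion rate
    between ``ied_rate_negative`` and ``ied_rate_positive``.
    """
    if rng is None:
        rng = np.random.default_rng(int(profile.get("recording_seed", config.seed)))
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    channels = CHANNELS_1020[: config.n_channels]
    annotations = build_annotations(config)
    last = max((a.onset_s + a.duration_s for a in annotations), default=0.0)
    if config.duration_s < last + 10.0:
        raise ConfigError("duration_s: must extend one epoch past the last annotation")

    risk = float(profile["latent_risk"])
    eff = config.effect_sizes
    alpha_shift_log10 = ALPHA_LOG10_POWER_PER_UNIT * eff.get("band_power", 0.0) * risk
    f_peak = _BASE_ALPHA_FREQ + eff.get("paf_hz", 0.0) * risk + rng.normal(0.0, 0.2)
    f_peak = float(np.clip(f_peak, 8.2, 12.8))
    alpha_amp = _BASE_ALPHA_AMP * 10 ** (
        0.5 * alpha_shift_log10 + rng.normal(0.0, _ALPHA_JITTER_LOG10 / 2.0)
    )
    beta_amp = (
        ENTROPY_OSC_AMP_PER_UNIT * eff.get("entropy", 0.0) * max(risk, 0.0)
        * _BACKGROUND_SD
    )

    alpha_src = narrowband_noise(n, fs, f_peak, _ALPHA_BANDWIDTH_HZ, rng)
    beta_src = np.zeros(n)
    if beta_amp > 0:
        f_beta = rng.uniform(*_ENTROPY_OSC_FREQ_HZ)
        beta_src = np.sin(
            2.0 * np.pi * f_beta * np.arange(n) / fs + rng.uniform(0.0, 2.0 * np.pi)
        )
    contrast_src = np.zeros(n)
    e_contrast = eff.get("bp_contrast", 0.0)
    if e_contrast != 0.0:
        f_center = float(
            np.clip(
                _BP_CONTRAST_BASE_HZ - BP_CONTRAST_HZ_PER_UNIT * e_contrast * risk,
                *_BP_CONTRAST_RANGE_HZ,
            )
        )
        contrast_src = _BP_CONTRAST_AMP * narrowband_noise(
            n, fs, f_center, _BP_CONTRAST_BW_HZ, rng
        )
    sig = np.empty((len(channels), n))
    for ci, ch in enumerate(channels):
        bg = (
            math.sqrt(1.0 - _BASE_AR_WEIGHT) * pink_noise(n, rng)
            + math.sqrt(_BASE_AR_WEIGHT) * ar1_noise(n, 0.95, rng)
        )
        sig[ci] = (
            _BACKGROUND_SD * bg
            + alpha_amp * _ALPHA_WEIGHTS.get(ch, 0.5) * alpha_src
            + beta_amp * _BETA_WEIGHTS.get(ch, 0.5) * beta_src
            + _BETA_WEIGHTS.get(ch, 0.5) * contrast_src
        )

    _insert_spike_waves(sig, channels, fs, config, risk, rng)
    _insert_artifacts(sig, fs, config, rng)

    return Recording(
        eeg_id=str(profile["eeg_id"]),
        patient_id=str(profile["patient_id"]),
        sampling_rate=fs,
        channel_labels=tuple(channels),
        signal=sig,
        annotations=annotations,
    )


def spike_wave_template(fs: float, amplitude: float) -> np.ndarray:
    """70 ms triangular spike followed by a 300 ms half-sine slow wave."""
    n_spike = max(3, int(round(0.070 * fs)))
    n_wave = int(round(0.300 * fs))
    spike = amplitude * (1.0 - np.abs(np.linspace(-1, 1, n_spike)))
    wave = 0.6 * amplitude * np.sin(np.linspace(0.0, np.pi, n_wave))
    return np.concatenate([spike, wave])


def _insert_spike_waves(sig, channels, fs, config, risk, rng) -> None:
    rate = config.ied_rate_negative + (
        config.ied_rate_positive - config.ied_rate_negative
    ) * float(np.clip(risk, 0.0, 1.0))
    n_events = rng.poisson(rate * config.duration_s / 60.0)
    if n_events == 0:
        return
    template = spike_wave_template(fs, 3.0 * _BACKGROUND_SD)
    n = sig.shape[1]
    index = {ch: i for i, ch in enumerate(channels)}
    for _ in range(n_events):
        focus = channels[rng.integers(len(channels))]
        spread = [(focus, 1.0)] + [
            (nb, w) for nb, w in zip(_NEIGHBORS[focus], (0.6, 0.5, 0.4)) if nb in index
        ]
        start = rng.integers(0, n - template.size)
        for ch, w in spread:
            sig[index[ch], start : start + template.size] += w * template


def _insert_artifacts(sig, fs, config, rng) -> None:
    n_events = rng.poisson(config.artifact_rate * config.duration_s / 60.0)
    n = sig.shape[1]
    for _ in range(n_events):
        width = int(round(rng.uniform(0.5, 2.0) * fs))
        start = rng.integers(0, max(1, n - width))
        n_ch = rng.integers(1, 4)
        rows = rng.choice(sig.shape[0], size=n_ch, replace=False)
        polarity = rng.choice([-1.0, 1.0])
        sig[rows, start : start + width] += polarity * 10.0 * _BACKGROUND_SD


# ---------------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------------


def simulate_outcomes(
    latent_risk: np.ndarray,
    survival_params: SurvivalParams,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Exponential recurrence times with independent uniform censoring.

    Event time ~ Exp(lambda0 * exp(beta * risk)); follow-up is drawn
    independently; ``outcome_recurrence_1y`` is true when an observed event
    falls within 52 weeks.
    """
    lam0 = survival_params.baseline_hazard_per_week
    if lam0 is None or lam0 <= 0:
        raise ConfigError("survival.baseline_hazard_per_week must be a positive number")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    risk = np.asarray(latent_risk, dtype=np.float64)
    lam = lam0 * np.exp(survival_params.log_hazard_per_risk * risk)
    event_time = rng.exponential(1.0 / lam)
    lo, hi = survival_params.followup_range_weeks
    followup = rng.uniform(lo, hi, size=risk.size)
    observed = event_time <= followup
    time = np.minimum(event_time, followup)
    return pd.DataFrame(
        {
            "time_to_event_weeks": time,
            "event_observed": observed,
            "followup_weeks": followup,
            "outcome_recurrence_1y": observed & (time <= 52.0),
        }
    )


def calibrate_baseline_hazard(
    prevalence: float,
    beta: float,
    followup_range: tuple[float, float],
    case_risk_mean: float = 1.0,
    control_risk_mean: float = 0.0,
    risk_sd: float = _RISK_NOISE_SD,
) -> float:
    """Baseline hazard giving the target expected one-year recurrence.

    Solves E[1 - exp(-lambda0 e^{beta r} min(52, U))] = prevalence by
    quadrature over the latent-risk mixture and the censoring distribution.
    """
    if not 0.0 < prevalence < 1.0:
        return 0.01
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    lo, hi = followup_range
    u_grid = np.linspace(lo, hi, 41) if hi > lo else np.array([lo])
    horizon = np.minimum(52.0, u_grid)

    def expected(lam0: float) -> float:
        total = 0.0
        for mean, mass in (
            (case_risk_mean, prevalence),
            (control_risk_mean, 1.0 - prevalence),
        ):
            r = mean + risk_sd * nodes
            lam = lam0 * np.exp(beta * r)  # (nodes,)
            probs = 1.0 - np.exp(-np.outer(lam, horizon))
            over_u = probs.mean(axis=1)
            total += mass * float(np.sum(weights / weights.sum() * over_u))
        return total

    try:
        return float(optimize.brentq(lambda l: expected(l) - prevalence, 1e-6, 5.0))
    except ValueError:
        return 0.01


def _conditional_survival(
    case: np.ndarray,
    risk: np.ndarray,
    params: SurvivalParams,
    prevalence: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Event times consistent with a pre-drawn one-year recurrence indicator."""
    lam0 = params.baseline_hazard_per_week
    if lam0 is None:
        lam0 = calibrate_baseline_hazard(
            prevalence, params.log_hazard_per_risk, params.followup_range_weeks
        )
    lam = lam0 * np.exp(params.log_hazard_per_risk * risk)
    lo, hi = params.followup_range_weeks
    followup = rng.uniform(lo, hi, size=risk.size)
    horizon = np.minimum(52.0, followup)
    n = risk.size
    time = np.empty(n)
    observed = np.zeros(n, dtype=bool)
    u = rng.uniform(size=n)
    for i in range(n):
        if case[i]:
            # event inside (0, horizon]: truncated exponential
            h = max(horizon[i], 1e-9)
            p_h = 1.0 - math.exp(-lam[i] * h)
            time[i] = -math.log(1.0 - u[i] * p_h) / lam[i] if p_h > 0 else h
            observed[i] = True
        else:
            if followup[i] > 52.0:
                later = 52.0 + rng.exponential(1.0 / lam[i])
                if later <= followup[i]:
                    time[i] = later
                    observed[i] = True
                else:
                    time[i] = followup[i]
            else:
                time[i] = followup[i]
    return pd.DataFrame(
        {
            "time_to_event_weeks": time,
            "event_observed": observed,
            "followup_weeks": followup,
            "outcome_recurrence_1y": observed & (time <= 52.0),
        }
    )


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "patient_id", "eeg_id", "cohort_split", "age", "sex", "asm_count",
    "ied_status", "focal_lesion", "slowing", "epilepsy_type",
    "outcome_recurrence_1y", "time_to_event_weeks", "event_observed",
    "followup_weeks", "latent_risk", "recording_seed",
)


def simulate_cohort_table(config: SimulationConfig) -> pd.DataFrame:
    """Clinical table of one synthetic cohort (no signals synthesized yet).

    One EEG per patient; the one-year recurrence indicator is Bernoulli at
    the configured prevalence and the censored event times are drawn
    consistently with it. ``recording_seed`` lets recordings be synthesized
    lazily yet reproducibly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    case = rng.uniform(size=n) < config.prevalence_recurrence
    risk = case.astype(float) + rng.normal(0.0, _RISK_NOISE_SD, size=n)
    age = np.clip(rng.normal(48.0, 18.0, size=n), 18.0, 90.0)
    sex = np.where(rng.uniform(size=n) < 0.5, "woman", "man")
    asm = rng.poisson(np.where(case, 1.5, 0.8))
    ied = np.where(
        case,
        rng.choice(["absent", "present", "uncertain"], size=n, p=[0.58, 0.35, 0.07]),
        rng.choice(["absent", "present", "uncertain"], size=n, p=[0.80, 0.12, 0.08]),
    )
    lesion = rng.uniform(size=n) < np.where(case, 0.40, 0.34)
    slowing = rng.uniform(size=n) < np.where(case, 0.28, 0.26)
    etype = np.where(
        case,
        rng.choice(["focal", "generalized", "unknown"], size=n, p=[0.67, 0.31, 0.02]),
        rng.choice(["focal", "generalized", "none", "unknown"], size=n,
                   p=[0.35, 0.13, 0.49, 0.03]),
    )
    surv = _conditional_survival(case, risk, config.survival,
                                 config.prevalence_recurrence, rng)
    n_train = int(round(n * (1.0 - config.test_fraction)))
    split = np.array(["train"] * n_train + ["test"] * (n - n_train))
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "eeg_id": [f"E{i + 1:04d}" for i in range(n)],
            "cohort_split": split,
            "age": age,
            "sex": sex,
            "asm_count": asm,
            "ied_status": ied,
            "focal_lesion": lesion,
            "slowing": slowing,
            "epilepsy_type": etype,
            "outcome_recurrence_1y": surv["outcome_recurrence_1y"].to_numpy(),
            "time_to_event_weeks": surv["time_to_event_weeks"].to_numpy(),
            "event_observed": surv["event_observed"].to_numpy(),
            "followup_weeks": surv["followup_weeks"].to_numpy(),
            "latent_risk": risk,
            "recording_seed": rng.integers(0, 2**31 - 1, size=n),
        }
    )
    return table


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[Recording]]:
    """Full cohort: clinical table plus synthesized annotated recordings."""
    table = simulate_cohort_table(config)
    recordings = [simulate_recording(row, config) for _, row in table.iterrows()]
    return table, recordings


def iter_recordings(table: pd.DataFrame, config: SimulationConfig) -> Iterator[Recording]:
    """Lazily synthesize recordings row by row (memory-friendly)."""
    for _, row in table.iterrows():
        yield simulate_recording(row, config)
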