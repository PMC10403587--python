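"""Recording-level preprocessing.

The protocol is: zero-phase FIR high-pass (0.75 Hz) and notch (60 Hz)
filtering, conversion to the average reference, extraction of 10-s epochs
at annotation-defined time points, and artifact handling via per-channel
peak-to-peak rejection thresholds tuned by cross-validation, with rejected
channel-epochs repaired by spherical-spline interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import eval_legendre

from .containers import Annotation, Epoch, Recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filtering and referencing
# ---------------------------------------------------------------------------


_filter_cache: dict[tuple, np.ndarray] = {}


def _hamming_fir(key, design) -> np.ndarray:
    taps = _filter_cache.get(key)
    if taps is None:
        taps = design()
        _filter_cache[key] = taps
    return taps


def filter_recording(
    recording: Recording,
    hp_cutoff_hz: float = 0.75,
    notch_hz: float | None = 60.0,
) -> Recording:
    """Zero-phase FIR (hamming-window design) high-pass then notch filter.

    The high-pass transition band (0.75 Hz wide) is centered on the cutoff;
    the notch is 2 Hz wide around the mains frequency. Linear-phase kernels
    applied with ``mode='same'`` preserve signal length with zero net delay.
    """
    from scipy.signal import fftconvolve, firwin

    fs = recording.sampling_rate
    nyq = fs / 2.0
    if hp_cutoff_hz >= nyq:
        raise ValueError(f"high-pass cutoff {hp_cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if notch_hz is not None and notch_hz >= nyq:
        raise ValueError(f"notch frequency {notch_hz} Hz >= Nyquist {nyq} Hz")

    hp_trans = 0.75
    n_hp = int(round(3.3 / hp_trans * fs)) | 1
    hp = _hamming_fir(
        ("hp", fs, hp_cutoff_hz),
        lambda: firwin(n_hp, hp_cutoff_hz, pass_zero=False, window="hamming", fs=fs),
    )
    sig = fftconvolve(recording.signal, hp[None, :], mode="same", axes=1)
    if notch_hz is not None:
        n_notch = int(round(3.3 / 1.0 * fs)) | 1
        notch = _hamming_fir(
            ("notch", fs, notch_hz),
            lambda: firwin(
                n_notch,
                [notch_hz - 1.0, notch_hz + 1.0],
                pass_zero=True,
                window="hamming",
                fs=fs,
            ),
        )
        sig = fftconvolve(sig, notch[None, :], mode="same", axes=1)
    return recording.copy_with(signal=sig)


def to_average_reference(recording: Recording) -> Recording:
    """Subtract the across-channel mean at every sample (average montage)."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    sig = recording.signal - recording.signal.mean(axis=0, keepdims=True)
    return recording.copy_with(signal=sig, reference="average")


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------

#: Seconds between epochs inside the hyperventilation / post-HV windows.
HV_STEP_S = 15.0
#: Length of the post-hyperventilation window (s).
POST_HV_WINDOW_S = 120.0


def _condition_of(label: str) -> Optional[str]:
    if label.startswith("montage"):
        return "montage_change"
    if label.startswith("hyperventilation") or label == "hv":
        return "hyperventilation"
    if label.startswith("photic"):
        return "photic"
    if label.startswith("eye"):
        return "eye_event"
    return None


def extract_epochs(recording: Recording, epoch_len_s: float = 10.0) -> list[Epoch]:
    """Cut fixed-length epochs at the protocol's annotation time points.

    One epoch starts at every montage change, photic-stimulation frequency
    and eye open/close event; a hyperventilation window of duration D yields
    epochs every 15 s while they fit inside the window, followed by
    post-hyperventilation epochs every 15 s over the 2 min after the window
    ends. Epochs that would overrun the recording are skipped.
    """
    duration = recording.duration_s
    fs = recording.sampling_rate
    n_len = int(round(epoch_len_s * fs))
    starts: list[tuple[float, str]] = []
    for ann in recording.annotations:
        condition = _condition_of(ann.label)
        if condition is None:
            continue
        if condition == "hyperventilation":
            offset = 0.0
            while offset + epoch_len_s <= ann.duration_s:
                starts.append((ann.onset_s + offset, "hyperventilation"))
                offset += HV_STEP_S
            hv_end = ann.onset_s + ann.duration_s
            offset = 0.0
            while offset + epoch_len_s <= POST_HV_WINDOW_S:
                starts.append((hv_end + offset, "post_hyperventilation"))
                offset += HV_STEP_S
        else:
            starts.append((ann.onset_s, condition))
    if not recording.annotations:
        logger.warning("extract_epochs: recording %s has no annotations", recording.eeg_id)

    starts.sort(key=lambda t: t[0])
    epochs: list[Epoch] = []
    for onset, condition in starts:
        i0 = int(round(onset * fs))
        if i0 + n_len > recording.n_samples or onset < 0:
            continue
        epochs.append(
            Epoch(
                eeg_id=recording.eeg_id,
                epoch_index=len(epochs),
                onset_s=onset,
                condition=condition,
                data=recording.signal[:, i0 : i0 + n_len].copy(),
                sampling_rate=fs,
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# Rejection thresholds
# ---------------------------------------------------------------------------


@dataclass
class ThresholdMap:
    """Per-channel peak-to-peak rejection thresholds (uV) with CV loss curves."""

    thresholds: np.ndarray  # (n_channels,)
    candidates: np.ndarray  # (n_candidates,)
    loss_curves: np.ndarray  # (n_channels, n_candidates)


def peak_to_peak(epochs: Sequence[Epoch]) -> np.ndarray:
    """(n_epochs, n_channels) matrix of per-channel peak-to-peak amplitudes."""
    return np.array([ep.data.max(axis=1) - ep.data.min(axis=1) for ep in epochs])


def fit_rejection_thresholds(
    epochs: Sequence[Epoch],
    k_folds: int = 5,
    candidate_grid: Optional[np.ndarray] = None,
    n_candidates: int = 40,
) -> ThresholdMap:
    """Cross-validated peak-to-peak threshold per channel.

    Candidates default to 40 log-spaced values between the 10th and 99.9th
    percentile of the observed channel peak-to-peak amplitudes. For each
    fold and candidate, the mean signal of retained training epochs is
    compared (RMSE) against the pointwise median of the validation epochs;
    per channel the candidate with minimal mean loss wins, ties going to
    the smallest candidate. A channel whose every candidate rejects all
    epochs falls back to the largest candidate with a warning.
    """
    n_epochs = len(epochs)
    if n_epochs < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} epochs, got {n_epochs}")
    ptp = peak_to_peak(epochs)
    n_channels = ptp.shape[1]
    if candidate_grid is None:
        lo, hi = np.percentile(ptp, [10.0, 99.9])
        lo = max(lo, 1e-12)
        hi = max(hi, lo * (1 + 1e-9))
        candidate_grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_candidates))
    candidates = np.asarray(candidate_grid, dtype=np.float64)

    data = np.stack([ep.data for ep in epochs])  # (n_epochs, n_ch, n_samp)
    fold_ids = np.arange(n_epochs) % k_folds
    losses = np.zeros((n_channels, candidates.size))
    counts = np.zeros((n_channels, candidates.size))
    for fold in range(k_folds):
        val = fold_ids == fold
        train = ~val
        if not val.any() or not train.any():
            continue
        val_median = np.median(data[val], axis=0)  # (n_ch, n_samp)
        for ci in range(n_channels):
            train_ptp = ptp[train, ci]
            train_data = data[train, ci, :]
            for gi, thr in enumerate(candidates):
                keep = train_ptp <= thr
                if not keep.any():
                    losses[ci, gi] += np.inf
                else:
                    mean_sig = train_data[keep].mean(axis=0)
                    losses[ci, gi] += np.sqrt(
                        np.mean((mean_sig - val_median[ci]) ** 2)
                    )
                counts[ci, gi] += 1
    with np.errstate(invalid="ignore"):
        losses = losses / np.maximum(counts, 1)

    thresholds = np.empty(n_channels)
    for ci in range(n_channels):
        curve = losses[ci]
        if not np.isfinite(curve).any():
            logger.warning(
                "fit_rejection_thresholds: channel %d rejects all epochs at every "
                "candidate; falling back to the maximum candidate", ci,
            )
            thresholds[ci] = candidates[-1]
        else:
            thresholds[ci] = candidates[int(np.argmin(curve))]
    return ThresholdMap(thresholds=thresholds, candidates=candidates, loss_curves=losses)


# ---------------------------------------------------------------------------
# Spherical-spline interpolation (Perrin-style)
# ---------------------------------------------------------------------------

_SPLINE_STIFFNESS = 4
_SPLINE_TERMS = 50
_SPLINE_REG = 1e-5


_positions_cache: dict[tuple[str, ...], np.ndarray] = {}


def electrode_positions(labels: Sequence[str]) -> np.ndarray:
    """Unit-sphere positions of 10-20 electrodes (sphere fitted to montage)."""
    key = tuple(labels)
    cached = _positions_cache.get(key)
    if cached is not None:
        return cached
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos]
    if missing:
        raise ValueError(f"no montage position for channels: {missing}")
    xyz = np.array([pos[l] for l in labels], dtype=np.float64)
    # algebraic sphere fit: ||x - c||^2 = r^2
    a = np.hstack([2 * xyz, np.ones((len(xyz), 1))])
    b = np.sum(xyz**2, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    u = xyz - center
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    _positions_cache[key] = u
    return u


def _g_matrix(cosang: np.ndarray) -> np.ndarray:
    n = np.arange(1, _SPLINE_TERMS + 1, dtype=np.float64)
    factors = (2 * n + 1) / (n * (n + 1)) ** _SPLINE_STIFFNESS / (4 * np.pi)
    out = np.zeros_like(cosang, dtype=np.float64)
    for ni, f in zip(n.astype(int), factors):
        out += f * eval_legendre(ni, cosang)
    return out


def spline_interpolation_matrix(
    positions: np.ndarray, good: np.ndarray, bad: np.ndarray
) -> np.ndarray:
    """Matrix mapping good-channel samples to interpolated bad-channel samples."""
    pg = positions[good]
    pb = positions[bad]
    g_gg = _g_matrix(np.clip(pg @ pg.T, -1.0, 1.0))
    g_bg = _g_matrix(np.clip(pb @ pg.T, -1.0, 1.0))
    n_good = pg.shape[0]
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg + _SPLINE_REG * np.eye(n_good)
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    p = np.hstack([g_bg, np.ones((pb.shape[0], 1))])
    return p @ np.linalg.solve(a, np.vstack([np.eye(n_good), np.zeros((1, n_good))]))


def repair_epochs(
    epochs: Sequence[Epoch],
    thresholds: ThresholdMap,
    channel_labels: Sequence[str],
    max_bad_fraction: float = 0.3,
) -> list[Epoch]:
    """Mask channel-epochs exceeding their threshold and repair them.

    Masked channels are re-estimated by spherical-spline interpolation from
    the remaining good channels; epochs with more than ``max_bad_fraction``
    of channels bad (or with no good channel at all) are dropped with a
    logged reason. Unmasked channels are never modified.
    """
    positions = electrode_positions(channel_labels)
    out: list[Epoch] = []
    n_dropped = 0
    for ep in epochs:
        ptp = ep.data.max(axis=1) - ep.data.min(axis=1)
        bad = ptp > thresholds.thresholds
        if bad.all():
            logger.info("repair_epochs: epoch %s/%d dropped (all channels bad)",
                        ep.eeg_id, ep.epoch_index)
            n_dropped += 1
            continue
        if bad.mean() > max_bad_fraction:
            logger.info(
                "repair_epochs: epoch %s/%d dropped (%d/%d channels bad)",
                ep.eeg_id, ep.epoch_index, int(bad.sum()), ep.n_channels,
            )
            n_dropped += 1
            continue
        data = ep.data.copy()
        if bad.any():
            good = ~bad
            interp = spline_interpolation_matrix(positions, good, bad)
            data[bad] = interp @ data[good]
        out.append(
            Epoch(
                eeg_id=ep.eeg_id,
                epoch_index=ep.epoch_index,
                onset_s=ep.onset_s,
                condition=ep.condition,
                data=data,
                sampling_rate=ep.sampling_rate,
                bad_channel_mask=bad,
                interpolated_channels=frozenset(np.flatnonzero(bad).tolist()),
            )
        )
    if n_dropped:
        logger.info("repair_epochs: dropped %d of %d epochs", n_dropped, len(epochs))
    return out
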