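"""The ten univariate EEG markers.

Linear markers — band power (BP) in ten bands, peak alpha frequency (PAF),
Hurst exponent (HE) — and non-linear markers — line length (LL), correlation
dimension (CD), approximate/sample/fuzzy/permutation/spectral entropy — are
computed per epoch and channel. BP and PAF operate on the raw epoch-channel
series; HE, LL, CD and the five entropies are computed on each of the six
Sym5 wavelet detail levels, yielding 59 values per channel and epoch.

Degenerate inputs follow explicit rules rather than propagating NaN
silently: a flat series has zero entropy and zero line length, while HE and
CD (undefined on a constant) are flagged missing.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy.integrate import simpson
from scipy.signal.windows import dpss

from ._entropy import (
    apen_phi,
    embedded_stats,
    pairwise_chebyshev,
    permutation_counts,
)
from .config import BandScheme, EntropyParams, WaveletSpec

logger = logging.getLogger(__name__)

MARKER_NAMES = (
    "BP", "PAF", "HE", "LL", "CD", "ApEn", "SampEn", "FuzzEn", "PermEn", "SpecEn",
)
#: Markers computed per wavelet detail level.
LEVEL_MARKERS = ("HE", "LL", "CD", "ApEn", "SampEn", "FuzzEn", "PermEn", "SpecEn")

#: Floor (uV^2) under which band power is clipped before taking log10.
BP_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Spectral estimation
# ---------------------------------------------------------------------------

_dpss_cache: dict[tuple[int, float, int], np.ndarray] = {}


def multitaper_psd(
    series: np.ndarray, fs: float, nw: float = 4.0, n_tapers: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper PSD (DPSS tapers, eigenvalue-unweighted average).

    Returns ``(freqs, psd)`` with the PSD scaled so that its integral over
    frequency approximates the series variance.
    """
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    key = (n, nw, n_tapers)
    tapers = _dpss_cache.get(key)
    if tapers is None:
        k = min(n_tapers, max(1, n - 1))
        tapers = dpss(n, nw, k)
        tapers = tapers / np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))
        _dpss_cache[key] = tapers
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2 / fs
    psd = spectra.mean(axis=0)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


_fir_cache: dict[tuple[float, float, float], np.ndarray] = {}


def _fir_bandpass(series: np.ndarray, fs: float, f_low: float, f_high: float) -> np.ndarray:
    """Zero-phase Hamming-window FIR band-pass (2 Hz transition bands)."""
    from scipy.signal import fftconvolve, firwin

    nyq = fs / 2.0
    hi = min(f_high, nyq * 0.999)
    key = (fs, f_low, hi)
    taps = _fir_cache.get(key)
    if taps is None:
        trans = 2.0
        numtaps = int(round(3.3 / trans * fs)) | 1  # odd length, linear phase
        taps = firwin(numtaps, [f_low, hi], pass_zero=False, window="hamming", fs=fs)
        _fir_cache[key] = taps
    return fftconvolve(np.asarray(series, dtype=np.float64), taps, mode="same")


def band_power(
    series: np.ndarray,
    scheme: BandScheme,
    fs: float,
    log: bool = True,
    prefilter: bool = False,
) -> np.ndarray:
    """Power per frequency band: multitaper PSD integrated by Simpson's rule.

    With ``prefilter=True`` the series is FIR band-pass filtered per band
    before estimating the PSD (the alternative reading of the protocol); the
    multitaper integral on the raw series is the default. Powers are
    reported as log10(uV^2) with a floor of ``BP_FLOOR`` unless ``log=False``.
    """
    x = np.asarray(series, dtype=np.float64)
    nyq = fs / 2.0
    out = np.empty(len(scheme.bands))
    if not prefilter:
        freqs, psd = multitaper_psd(x, fs)
    for b, (name, lo, hi) in enumerate(scheme.bands):
        if lo >= nyq:
            raise ValueError(f"band {name!r} lies above the Nyquist frequency {nyq} Hz")
        hi_eff = min(hi, nyq)
        if prefilter:
            freqs, psd = multitaper_psd(_fir_bandpass(x, fs, lo, hi_eff), fs)
        sel = (freqs >= lo) & (freqs < hi_eff)
        if sel.sum() < 2:
            power = 0.0
        else:
            power = float(simpson(psd[sel], x=freqs[sel]))
        out[b] = power
    if log:
        out = np.log10(np.maximum(out, BP_FLOOR))
    return out


def peak_alpha_frequency(series: np.ndarray, fs: float) -> float:
    """Frequency of the PSD maximum in the 8-13 Hz alpha band.

    The series is FIR band-pass filtered to 8-13 Hz first; exact ties go to
    the lower frequency. A value is always returned — on alpha-free input it
    is the argmax of broadband noise within the band (logged at debug level).
    """
    x = _fir_bandpass(series, fs, 8.0, 13.0)
    freqs, psd = multitaper_psd(x, fs)
    sel = (freqs >= 8.0) & (freqs <= 13.0)
    band_psd = psd[sel]
    peak = float(freqs[sel][int(np.argmax(band_psd))])
    if band_psd.max() < 2.0 * np.median(band_psd):
        logger.debug("peak_alpha_frequency: low-prominence alpha peak at %.2f Hz", peak)
    return peak


# ---------------------------------------------------------------------------
# Wavelet decomposition
# ---------------------------------------------------------------------------


def wavelet_decompose(series: np.ndarray, spec: WaveletSpec) -> list[np.ndarray]:
    """Detail-coefficient series D1..D6 of the discrete wavelet transform.

    Uses periodized convolution so the transform is orthonormal and the
    detail + final-approximation energies sum exactly to the input energy.
    D1 is the highest-frequency level (fs/4 .. fs/2).
    """
    x = np.asarray(series, dtype=np.float64)
    filt_len = pywt.Wavelet(spec.wavelet).dec_len
    min_len = (filt_len - 1) * 2**spec.n_levels
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} too short for {spec.n_levels} "
            f"{spec.wavelet} levels; need at least {min_len} samples"
        )
    coeffs = pywt.wavedec(x, spec.wavelet, mode="periodization", level=spec.n_levels)
    # wavedec returns [cA_L, cD_L, ..., cD_1]; reorder to D1..D_L
    return [coeffs[-lvl] for lvl in range(1, spec.n_levels + 1)]


# ---------------------------------------------------------------------------
# Fractal / waveform markers
# ---------------------------------------------------------------------------


def hurst_exponent(series: np.ndarray, min_window: int = 10) -> float:
    """Rescaled-range (R/S) Hurst estimate.

    R/S is averaged over non-overlapping windows at ~10 log-spaced window
    sizes from ``min_window`` to half the series length; H is the
    least-squares slope of log(R/S) against log(window size). Returns NaN
    for a constant series (R/S undefined).
    """
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    if n < 2 * min_window:
        raise ValueError(
            f"series of length {n} too short for Hurst estimation "
            f"(need >= {2 * min_window})"
        )
    sizes = np.unique(
        np.round(np.exp(np.linspace(np.log(min_window), np.log(n // 2), 10))).astype(int)
    )
    log_w, log_rs = [], []
    for w in sizes:
        k = n // w
        segs = x[: k * w].reshape(k, w)
        demeaned = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(demeaned, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = segs.std(axis=1)
        ok = s > 0
        if not ok.any():
            continue
        log_w.append(np.log(w))
        log_rs.append(np.log(np.mean(r[ok] / s[ok])))
    if len(log_w) < 2:
        return float("nan")
    slope = np.polyfit(log_w, log_rs, 1)[0]
    return float(slope)


def line_length(series: np.ndarray) -> float:
    """Sum of absolute successive differences (uV)."""
    x = np.asarray(series, dtype=np.float64)
    if x.size < 2:
        raise ValueError("line length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def correlation_dimension(series: np.ndarray, params: EntropyParams) -> float:
    """Grassberger-Procaccia correlation dimension.

    The series is delay-embedded with (m, tau); the correlation sum C(rho)
    is evaluated at 20 log-spaced radii between the 5th and 50th percentile
    of the pairwise Chebyshev distances, and CD is the least-squares slope
    of log C against log rho. NaN on (near-)constant input.
    """
    x = np.asarray(series, dtype=np.float64)
    m, tau = params.m, params.tau
    if x.size < (m - 1) * tau + 50:
        return float("nan")
    if np.std(x) == 0:
        return float("nan")
    return _cd_from_dists(pairwise_chebyshev(x, m, tau))


def _cd_from_dists(dists: np.ndarray) -> float:
    # deterministic strided subsample keeps the correlation sum O(1e5)
    stride = max(1, dists.size // 50_000)
    if stride > 1:
        dists = dists[::stride]
    lo, hi = np.percentile(dists, [5.0, 50.0])
    if lo <= 0:
        pos = dists[dists > 0]
        if pos.size == 0:
            return float("nan")
        lo = pos.min()
    if hi <= lo:
        return float("nan")
    radii = np.exp(np.linspace(np.log(lo), np.log(hi), 20))
    log_r, log_c = [], []
    n_pairs = dists.size
    for rho in radii:
        c = np.count_nonzero(dists < rho) / n_pairs
        if c > 0:
            log_r.append(np.log(rho))
            log_c.append(np.log(c))
    if len(log_r) < 2:
        return float("nan")
    return float(np.polyfit(log_r, log_c, 1)[0])


# ---------------------------------------------------------------------------
# Entropies
# ---------------------------------------------------------------------------

ENTROPY_KINDS = ("approximate", "sample", "fuzzy", "permutation", "spectral")


def entropy(
    series: np.ndarray,
    kind: str,
    params: EntropyParams,
    fs: float = 1.0,
) -> float:
    """One of the five entropy estimates.

    Embedded kinds (approximate, sample, fuzzy) use tolerance
    ``r * SD(series)``, Chebyshev distance and delay ``tau``; permutation
    entropy is normalized by log(k!) and spectral entropy by the log number
    of spectral bins, so both lie in [0, 1]. A constant series scores 0 for
    every kind; series shorter than the embedding requires return NaN.
    """
    if kind not in ENTROPY_KINDS:
        raise ValueError(f"unknown entropy kind {kind!r}")
    x = np.asarray(series, dtype=np.float64)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    m, tau, k = params.m, params.tau, params.k

    if kind == "permutation":
        if x.size < (k - 1) * tau + 1:
            return float("nan")
        counts = permutation_counts(x, k, tau)
        p = counts[counts > 0] / counts.sum()
        h = -float(np.sum(p * np.log(p)))
        return h / np.log(float(math.factorial(k))) if k > 1 else 0.0

    if kind == "spectral":
        if x.size < 8:
            return float("nan")
        freqs, psd = multitaper_psd(x, fs)
        psd = psd[1:]  # drop DC
        total = psd.sum()
        if total <= 0:
            return 0.0
        p = psd / total
        p = p[p > 0]
        return -float(np.sum(p * np.log(p))) / np.log(psd.size)

    r_abs = params.r * sd
    if kind == "approximate" and x.size == m * tau + 1:
        # single template at dimension m+1; the fused kernel needs two
        return float(apen_phi(x, m, tau, r_abs) - apen_phi(x, m + 1, tau, r_abs))
    if x.size < m * tau + 2:
        return float("nan")
    stats = _embedded_stats_from(x, params, r_abs)
    return stats[kind]


def _embedded_stats_from(x: np.ndarray, params: EntropyParams, r_abs: float) -> dict:
    """ApEn/SampEn/FuzzEn (and CD) from one fused template-matching pass."""
    m, tau = params.m, params.tau
    dists, apen_cm, apen_cm1, a, b, fuzz_dm, fuzz_dm1 = embedded_stats(
        x, m, tau, r_abs
    )
    n_m = x.size - (m - 1) * tau
    n_m1 = x.size - m * tau
    apen = float(
        np.mean(np.log(apen_cm / n_m)) - np.mean(np.log(apen_cm1 / n_m1))
    )
    sampen = float(-np.log(a / b)) if a > 0 and b > 0 else float("nan")
    n_pairs = n_m1 * (n_m1 - 1) / 2.0
    phi_m = float(np.sum(np.exp(-((fuzz_dm / r_abs) ** params.n)))) / n_pairs
    phi_m1 = float(np.sum(np.exp(-((fuzz_dm1 / r_abs) ** params.n)))) / n_pairs
    fuzzen = (
        float(np.log(phi_m) - np.log(phi_m1))
        if phi_m > 0 and phi_m1 > 0
        else float("nan")
    )
    return {
        "approximate": apen,
        "sample": sampen,
        "fuzzy": fuzzen,
        "_dists": dists,
    }


# ---------------------------------------------------------------------------
# Tensor extraction
# ---------------------------------------------------------------------------

_ENTROPY_BY_MARKER = {
    "ApEn": "approximate",
    "SampEn": "sample",
    "FuzzEn": "fuzzy",
    "PermEn": "permutation",
    "SpecEn": "spectral",
}


def extract_marker_tensor(
    epochs: Iterable,
    channel_labels: Sequence[str],
    wavelet_spec: Optional[WaveletSpec] = None,
    band_scheme: Optional[BandScheme] = None,
    entropy_params: Optional[EntropyParams] = None,
    markers: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Marker tensor in long format over (epoch, channel, marker, sub-index).

    BP and PAF are computed on the raw epoch-channel series; the remaining
    eight markers on each wavelet detail level (sub-index ``L1``..``L6``).
    Degenerate series yield flagged-missing rows, never exceptions.
    """
    wavelet_spec = wavelet_spec or WaveletSpec()
    band_scheme = band_scheme or BandScheme()
    entropy_params = entropy_params or EntropyParams()
    selected = tuple(markers) if markers is not None else MARKER_NAMES
    unknown = set(selected) - set(MARKER_NAMES)
    if unknown:
        raise ValueError(f"unknown markers: {sorted(unknown)}")

    rows: list[tuple] = []

    def emit(epoch, channel, marker, sub_index, value):
        missing = not np.isfinite(value)
        rows.append(
            (
                epoch.eeg_id,
                epoch.epoch_index,
                channel,
                marker,
                sub_index,
                float(value) if not missing else np.nan,
                missing,
            )
        )

    level_markers = [mk for mk in LEVEL_MARKERS if mk in selected]
    for epoch in epochs:
        fs = epoch.sampling_rate
        for ci, channel in enumerate(channel_labels):
            x = epoch.data[ci]
            if "BP" in selected:
                powers = band_power(x, band_scheme, fs)
                for name, p in zip(band_scheme.names, powers):
                    emit(epoch, channel, "BP", name, p)
            if "PAF" in selected:
                if np.std(x) == 0:
                    emit(epoch, channel, "PAF", "-", np.nan)
                else:
                    emit(epoch, channel, "PAF", "-", peak_alpha_frequency(x, fs))
            if not level_markers:
                continue
            try:
                levels = wavelet_decompose(x, wavelet_spec)
            except ValueError:
                for lvl in range(1, wavelet_spec.n_levels + 1):
                    for mk in level_markers:
                        emit(epoch, channel, mk, f"L{lvl}", np.nan)
                continue
            m, tau = entropy_params.m, entropy_params.tau
            for lvl, d in enumerate(levels, start=1):
                sub = f"L{lvl}"
                level_fs = fs / 2**lvl
                sd = float(np.std(d))
                emb = None
                if (
                    sd > 0
                    and d.size >= m * tau + 2
                    and any(mk in level_markers for mk in ("ApEn", "SampEn", "FuzzEn", "CD"))
                ):
                    emb = _embedded_stats_from(d, entropy_params, entropy_params.r * sd)
                for mk in level_markers:
                    if mk == "HE":
                        try:
                            val = hurst_exponent(d)
                        except ValueError:
                            val = np.nan
                    elif mk == "LL":
                        val = line_length(d)
                    elif mk == "CD":
                        if sd == 0 or d.size < (m - 1) * tau + 50 or emb is None:
                            val = np.nan
                        else:
                            val = _cd_from_dists(emb["_dists"])
                    elif mk in ("ApEn", "SampEn", "FuzzEn"):
                        if sd == 0:
                            val = 0.0
                        elif emb is None:
                            val = np.nan
                        else:
                            val = emb[_ENTROPY_BY_MARKER[mk]]
                    else:
                        val = entropy(d, _ENTROPY_BY_MARKER[mk], entropy_params, fs=level_fs)
                    emit(epoch, channel, mk, sub, val)

    tensor = pd.DataFrame(
        rows,
        columns=[
            "eeg_id", "epoch_index", "channel", "marker", "sub_index",
            "value", "missing",
        ],
    )
    n_missing = int(tensor["missing"].sum())
    if n_missing:
        logger.info("marker tensor: %d of %d values flagged missing", n_missing, len(tensor))
    return tensor


# ---------------------------------------------------------------------------
# Entropy-parameter selection
# ---------------------------------------------------------------------------


def select_entropy_params(
    epochs_by_recording: dict[str, list],
    grid: Sequence[EntropyParams],
    calibration_level: Optional[int] = 3,
    wavelet_spec: Optional[WaveletSpec] = None,
) -> EntropyParams:
    """Choose entropy parameters maximizing inter- vs intra-recording variance.

    For each candidate, the four embedded entropies are computed per epoch
    and channel on one wavelet detail level (default level 3, 25-12.5 Hz at
    200 Hz — fast yet within the EEG band; ``calibration_level=None`` uses
    the raw series); the score is the variance of per-recording means
    divided by the mean within-recording variance, averaged over channels
    and entropy kinds. Returns the argmax candidate.
    """
    if len(epochs_by_recording) < 2:
        raise ValueError("need at least 2 calibration recordings")
    if any(len(eps) < 2 for eps in epochs_by_recording.values()):
        raise ValueError("need at least 2 epochs per calibration recording")
    if not grid:
        raise ValueError("empty parameter grid")
    wavelet_spec = wavelet_spec or WaveletSpec()
    kinds = ("approximate", "sample", "fuzzy", "permutation")

    # Pre-decompose once; the wavelet does not depend on the candidate params.
    series: dict[str, list[list[np.ndarray]]] = {}
    for rec_id, eps in epochs_by_recording.items():
        series[rec_id] = [
            [
                ep.data[ci]
                if calibration_level is None
                else wavelet_decompose(ep.data[ci], wavelet_spec)[calibration_level - 1]
                for ci in range(ep.n_channels)
            ]
            for ep in eps
        ]

    best, best_score = None, -np.inf
    for cand in grid:
        scores = []
        n_channels = next(iter(epochs_by_recording.values()))[0].n_channels
        for kind in kinds:
            for ci in range(n_channels):
                rec_means, rec_vars = [], []
                for rec_id in epochs_by_recording:
                    vals = np.array(
                        [entropy(s[ci], kind, cand) for s in series[rec_id]]
                    )
                    vals = vals[np.isfinite(vals)]
                    if vals.size < 2:
                        continue
                    rec_means.append(vals.mean())
                    rec_vars.append(vals.var(ddof=1))
                if len(rec_means) < 2:
                    continue
                within = float(np.mean(rec_vars))
                if within > 0:
                    scores.append(float(np.var(rec_means, ddof=1)) / within)
        if not scores:
            continue  # candidate saturates every entropy; not scoreable
        score = float(np.mean(scores))
        if score > best_score:
            best, best_score = cand, score
    if best is None:
        raise ValueError(
            "zero within-recording variance for every candidate/channel/kind; "
            "cannot score entropy parameters"
        )
    return best


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_missing(
    train: pd.DataFrame | np.ndarray,
    test: Optional[pd.DataFrame | np.ndarray] = None,
    seed: int = 0,
):
    """Multivariate iterative (chained-ridge) imputation.

    Missing cells start at column means and are refined by column-wise ridge
    regressions until the largest change falls below 1e-3 (at most 10
    sweeps). The imputer is fitted on ``train`` only and applied unchanged
    to ``test``. Columns that are entirely missing are filled with 0 and a
    warning is logged.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import Ridge

    train_arr = np.asarray(train, dtype=np.float64)
    test_arr = None if test is None else np.asarray(test, dtype=np.float64)
    if not np.isnan(train_arr).any() and (test_arr is None or not np.isnan(test_arr).any()):
        return (train, test) if test is not None else train

    all_missing = np.isnan(train_arr).all(axis=0)
    if all_missing.any():
        logger.warning(
            "impute_missing: %d all-missing column(s) filled with 0",
            int(all_missing.sum()),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        imputer = IterativeImputer(
            estimator=Ridge(alpha=1.0),
            max_iter=10,
            tol=1e-3,
            initial_strategy="mean",
            keep_empty_features=True,
            random_state=seed,
        )
        out_train = imputer.fit_transform(train_arr)
        out_test = None if test_arr is None else imputer.transform(test_arr)

    def _wrap(arr, like):
        if isinstance(like, pd.DataFrame):
            return pd.DataFrame(arr, index=like.index, columns=like.columns)
        return arr

    if test is not None:
        return _wrap(out_train, train), _wrap(out_test, test)
    return _wrap(out_train, train)


def tensor_to_features(tensor: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format marker tensor to an epoch-level feature matrix.

    Rows are (eeg_id, epoch_index); columns are ``channel|marker|sub_index``.
    Missing values remain NaN for downstream imputation.
    """
    named = tensor.assign(
        feature=tensor["channel"].astype(str)
        + "|"
        + tensor["marker"].astype(str)
        + "|"
        + tensor["sub_index"].astype(str)
    )
    wide = named.pivot(
        index=["eeg_id", "epoch_index"], columns="feature", values="value"
    )
    wide.columns.name = None
    return wide.sort_index(axis=1)
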