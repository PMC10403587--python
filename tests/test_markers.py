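"""Marker estimators: oracle equivalence, invariances, degenerate rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegprognosis.config import BandScheme, EntropyParams, WaveletSpec
from eegprognosis.markers import (
    band_power,
    correlation_dimension,
    entropy,
    extract_marker_tensor,
    hurst_exponent,
    impute_missing,
    line_length,
    multitaper_psd,
    peak_alpha_frequency,
    select_entropy_params,
    tensor_to_features,
    wavelet_decompose,
)
from eegprognosis.containers import Epoch
from eegprognosis.validation import (
    naive_apen,
    naive_fuzzen,
    naive_permen,
    naive_sampen,
)

PARAMS = EntropyParams()
FS = 200.0
T10 = np.arange(2000) / FS


def _series_cases(rng):
    yield rng.standard_normal(80)
    yield np.sin(0.37 * np.arange(64)) + 0.2 * rng.standard_normal(64)
    yield np.round(rng.standard_normal(100), 1)  # heavy ties
    yield rng.exponential(size=50)


@pytest.mark.parametrize(
    "kind,oracle",
    [
        ("approximate", lambda x, p, r: naive_apen(x, p, r)),
        ("sample", lambda x, p, r: naive_sampen(x, p, r)),
        ("fuzzy", lambda x, p, r: naive_fuzzen(x, p, r)),
        ("permutation", lambda x, p, r: naive_permen(x, p)),
    ],
)
def test_entropy_matches_bruteforce_oracle(kind, oracle, rng):
    """Fast kernels agree with naive template counting to 1e-10."""
    for x in _series_cases(rng):
        fast = entropy(x, kind, PARAMS)
        slow = oracle(x, PARAMS, PARAMS.r * x.std())
        if np.isnan(fast) and np.isnan(slow):
            continue
        assert fast == pytest.approx(slow, abs=1e-10)


def test_entropy_affine_invariance(rng):
    """Relative-tolerance entropies are invariant to positive affine maps."""
    x = rng.standard_normal(120)
    y = 7.3 * x - 11.0
    for kind in ("approximate", "sample", "fuzzy", "permutation"):
        assert entropy(x, kind, PARAMS) == pytest.approx(
            entropy(y, kind, PARAMS), abs=1e-9
        )


def test_entropy_normalized_ranges(rng):
    x = rng.standard_normal(500)
    assert 0.0 <= entropy(x, "permutation", PARAMS) <= 1.0
    assert 0.0 <= entropy(x, "spectral", PARAMS, fs=FS) <= 1.0


def test_entropy_degenerate_rules():
    flat = np.full(300, 2.5)
    for kind in ("approximate", "sample", "fuzzy", "permutation", "spectral"):
        assert entropy(flat, kind, PARAMS) == 0.0
    assert np.isnan(entropy(np.array([1.0, 2.0, 3.0]), "sample", PARAMS))


def test_permutation_entropy_of_monotone_series_is_zero():
    assert entropy(np.arange(100.0), "permutation", PARAMS) == 0.0


def test_sampen_orders_noise_above_sine(rng):
    wins = 0
    for k in range(8):
        r = np.random.default_rng(k)
        noise = r.standard_normal(1500)
        sine = np.sin(2 * np.pi * 10 * np.arange(1500) / FS + r.uniform(0, 6.28))
        noise, sine = noise / noise.std(), sine / sine.std()
        wins += entropy(noise, "sample", PARAMS) > entropy(sine, "sample", PARAMS)
    assert wins >= 7


def test_spectral_entropy_noise_above_sine(rng):
    noise = rng.standard_normal(2000)
    sine = np.sin(2 * np.pi * 10 * T10)
    assert entropy(noise, "spectral", PARAMS, fs=FS) > entropy(
        sine, "spectral", PARAMS, fs=FS
    )


# -- wavelets ---------------------------------------------------------------


def test_wavelet_energy_conservation(rng):
    # length divisible by 2^6: the periodized transform is exactly orthogonal
    import pywt

    x = rng.standard_normal(2048)
    coeffs = pywt.wavedec(x, "sym5", mode="periodization", level=6)
    total = sum(np.sum(c**2) for c in coeffs)
    assert total == pytest.approx(np.sum(x**2), rel=1e-8)
    levels = wavelet_decompose(x, WaveletSpec())
    detail = sum(np.sum(d**2) for d in levels)
    assert detail == pytest.approx(total - np.sum(coeffs[0] ** 2), rel=1e-8)


def test_wavelet_sine_concentrates_in_level4():
    x = np.sin(2 * np.pi * 10 * T10)  # 10 Hz -> level 4 covers 12.5-6.25 Hz
    levels = wavelet_decompose(x, WaveletSpec())
    energies = [np.sum(d**2) for d in levels]
    assert int(np.argmax(energies)) == 3


def test_wavelet_zero_input_and_short_series_error():
    assert all(
        np.allclose(d, 0) for d in wavelet_decompose(np.zeros(1000), WaveletSpec())
    )
    with pytest.raises(ValueError, match="at least"):
        wavelet_decompose(np.zeros(100), WaveletSpec())


# -- band power and PAF -----------------------------------------------------


def test_band_power_tone_lands_in_low_alpha():
    x = np.sin(2 * np.pi * 9 * T10)
    raw = band_power(x, BandScheme(), FS, log=False)
    assert raw[4] / raw.sum() >= 0.90  # low alpha [8, 10)


def test_band_power_zero_signal_floors():
    out = band_power(np.zeros(2000), BandScheme(), FS)
    assert np.allclose(out, -12.0)


def test_band_power_white_noise_parseval(rng):
    """Summed band power over 1-100 Hz tracks the in-range variance."""
    scheme = BandScheme()
    rel_errs = []
    for k in range(10):
        r = np.random.default_rng(k)
        x = r.standard_normal(2000) * 3.0
        raw = band_power(x, scheme, FS, log=False)
        freqs, psd = multitaper_psd(x, FS)
        in_range = psd[(freqs >= 1.0) & (freqs < 100.0)].sum() * (freqs[1] - freqs[0])
        rel_errs.append(abs(raw.sum() - in_range) / in_range)
    assert np.mean(rel_errs) < 0.10


def test_band_above_nyquist_errors():
    scheme = BandScheme(bands=(("hf", 120.0, 150.0),))
    with pytest.raises(ValueError, match="Nyquist"):
        band_power(np.zeros(2000), scheme, FS)


def test_peak_alpha_frequency_tone_and_range(rng):
    assert peak_alpha_frequency(np.sin(2 * np.pi * 9.5 * T10), FS) == pytest.approx(
        9.5, abs=0.1
    )
    vals = [
        peak_alpha_frequency(np.random.default_rng(k).standard_normal(2000), FS)
        for k in range(20)
    ]
    assert all(8.0 <= v <= 13.0 for v in vals)


def test_peak_alpha_tie_goes_to_lower_frequency():
    # a perfectly flat in-band PSD (zero signal) is an exact all-way tie;
    # the documented rule returns the lowest candidate frequency
    assert peak_alpha_frequency(np.zeros(2000), FS) == pytest.approx(8.0)


# -- Hurst / LL / CD --------------------------------------------------------


def test_hurst_white_noise_near_half():
    ests = [
        hurst_exponent(np.random.default_rng(k).standard_normal(2000))
        for k in range(30)
    ]
    assert np.mean(ests) == pytest.approx(0.5, abs=0.1)


def test_hurst_random_walk_high():
    ests = [
        hurst_exponent(np.cumsum(np.random.default_rng(k).standard_normal(2000)))
        for k in range(10)
    ]
    assert np.mean(ests) > 0.85


def test_hurst_short_series_errors():
    with pytest.raises(ValueError, match="too short"):
        hurst_exponent(np.arange(19.0))
    assert np.isnan(hurst_exponent(np.full(200, 1.0)))


def test_line_length_examples(rng):
    assert line_length(np.full(50, 3.0)) == 0.0
    assert line_length(np.array([0.0, 1.0, 0.0, 1.0])) == 3.0
    x = rng.standard_normal(100)
    assert line_length(-2.5 * x) == pytest.approx(2.5 * line_length(x), rel=1e-12)


def test_correlation_dimension_limits():
    iid = [
        correlation_dimension(np.random.default_rng(k).standard_normal(1000), PARAMS)
        for k in range(10)
    ]
    assert 2.2 <= np.mean(iid) <= 3.2
    sine = correlation_dimension(np.sin(2 * np.pi * 7 * T10), PARAMS)
    assert 0.7 <= sine <= 1.4
    assert np.isnan(correlation_dimension(np.full(500, 1.0), PARAMS))


# -- tensor extraction ------------------------------------------------------


def test_marker_tensor_layout_and_determinism(noise_epoch, channels):
    tensor = extract_marker_tensor([noise_epoch], channels)
    assert len(tensor) == 19 * 59  # 10 BP + 1 PAF + 6*(8 level markers)
    again = extract_marker_tensor([noise_epoch], channels)
    pd.testing.assert_frame_equal(tensor, again)
    wide = tensor_to_features(tensor)
    assert wide.shape == (1, 19 * 59)


def test_marker_tensor_flat_channel_degenerate_rules(noise_epoch, channels):
    noise_epoch.data[3] = 0.0
    tensor = extract_marker_tensor([noise_epoch], channels).set_index(
        ["channel", "marker", "sub_index"]
    )
    ch = channels[3]
    assert tensor.loc[(ch, "HE", "L1"), "missing"].item()
    assert tensor.loc[(ch, "CD", "L1"), "missing"].item()
    assert tensor.loc[(ch, "LL", "L1"), "value"].item() == 0.0
    assert tensor.loc[(ch, "SampEn", "L1"), "value"].item() == 0.0


def test_marker_subset_selection(noise_epoch, channels):
    tensor = extract_marker_tensor([noise_epoch], channels, markers=("BP", "PAF"))
    assert set(tensor["marker"]) == {"BP", "PAF"}
    assert len(tensor) == 19 * 11
    with pytest.raises(ValueError, match="unknown markers"):
        extract_marker_tensor([noise_epoch], channels, markers=("BP", "XX"))


# -- entropy parameter selection -------------------------------------------


def _calibration_epochs(rng, smooth: bool, n_epochs=3):
    eps = []
    for i in range(n_epochs):
        if smooth:
            base = np.cumsum(rng.standard_normal((4, 2000)), axis=1)
            base = base / base.std(axis=1, keepdims=True)
        else:
            base = rng.standard_normal((4, 2000))
        eps.append(
            Epoch(
                eeg_id="X",
                epoch_index=i,
                onset_s=0.0,
                condition="montage_change",
                data=10 * base,
                sampling_rate=200.0,
            )
        )
    return eps


def test_select_entropy_params_grid_of_one_and_symmetry(rng):
    recs = {
        "A": _calibration_epochs(rng, smooth=False),
        "B": _calibration_epochs(rng, smooth=True),
    }
    only = EntropyParams()
    assert select_entropy_params(recs, [only]) is only
    grid = [EntropyParams(), EntropyParams(tau=1)]
    first = select_entropy_params(dict(recs), grid)
    relabeled = select_entropy_params(dict(reversed(list(recs.items()))), grid)
    assert first is relabeled


def _lagged_epochs(rng, lag_weight, n_epochs=3, n=400):
    """Epochs whose only structure is dependence at lag 5 samples."""
    eps = []
    for i in range(n_epochs):
        z = rng.standard_normal((1, n + 5))
        x = z[:, 5:] + lag_weight * z[:, :-5]
        eps.append(Epoch("X", i, 0.0, "montage_change", 10 * x, 200.0))
    return eps


def test_select_entropy_params_finds_discriminative_delay(rng):
    """Recording classes differing only at a 5-sample timescale: the
    variance-ratio criterion should pick the tau=5 embedding over tau=1
    in at least 8 of 10 repeats."""
    grid = [EntropyParams(tau=1), EntropyParams(tau=5)]
    wins = 0
    for rep in range(10):
        r = np.random.default_rng(rep)
        recs = {
            "A": _lagged_epochs(r, 0.0), "B": _lagged_epochs(r, 0.9),
            "C": _lagged_epochs(r, 0.0), "D": _lagged_epochs(r, 0.9),
        }
        wins += select_entropy_params(recs, grid, calibration_level=None).tau == 5
    assert wins >= 8


def test_select_entropy_params_preconditions(rng):
    recs = {"A": _calibration_epochs(rng, smooth=False)}
    with pytest.raises(ValueError, match="2 calibration recordings"):
        select_entropy_params(recs, [EntropyParams()])


# -- imputation -------------------------------------------------------------


def test_impute_noop_without_missing(rng):
    df = pd.DataFrame(rng.standard_normal((20, 4)))
    out = impute_missing(df, seed=0)
    pd.testing.assert_frame_equal(out, df)


def test_impute_recovers_correlated_column(rng):
    a = rng.standard_normal(200)
    df = pd.DataFrame({"a": a, "b": 2 * a + 1e-3 * rng.standard_normal(200)})
    truth = df.iloc[5, 1]
    df.iloc[5, 1] = np.nan
    out = impute_missing(df, seed=0)
    assert out.iloc[5, 1] == pytest.approx(truth, abs=1e-2)
    again = impute_missing(df, seed=0)
    pd.testing.assert_frame_equal(out, again)


def test_impute_train_test_contract(rng):
    train = pd.DataFrame(rng.standard_normal((50, 3)))
    test = pd.DataFrame(rng.standard_normal((10, 3)))
    test.iloc[0, 2] = np.nan
    out_train, out_test = impute_missing(train, test, seed=0)
    pd.testing.assert_frame_equal(out_train, train)
    assert not out_test.isna().any().any()


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
def test_permutation_entropy_affine_invariant_property(scale, offset):
    x = np.random.default_rng(7).standard_normal(150)
    assert entropy(scale * x + offset, "permutation", PARAMS) == pytest.approx(
        entropy(x, "permutation", PARAMS), abs=1e-12
    )
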