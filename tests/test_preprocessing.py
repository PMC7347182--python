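"""Preprocessing chain: filtering, adaptive cancellation, feature extraction,
Hampel outlier removal and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painemg.config import HampelParams
from painemg.preprocessing import (adaptive_noise_cancel, extract_features,
                                   hampel_filter, highpass_filter, rms_feature,
                                   wl_feature, zscore_standardize)

FS = 1000.0


# ---------------------------------------------------------------------------
# high-pass filter

def test_highpass_rejects_dc():
    x = np.full(5000, 7.3)
    y = highpass_filter(x, FS)
    assert np.max(np.abs(y[500:-500])) < 1e-6 * 7.3


def test_highpass_preserves_100hz():
    t = np.arange(10_000) / FS
    x = np.sin(2 * np.pi * 100 * t)
    y = highpass_filter(x, FS)
    mid = slice(2000, 8000)
    ratio = np.abs(y[mid]).max() / np.abs(x[mid]).max()
    assert abs(ratio - 1.0) < 0.01


def test_highpass_attenuates_2hz_by_30db():
    t = np.arange(30_000) / FS
    x = np.sin(2 * np.pi * 2 * t)
    y = highpass_filter(x, FS)
    mid = slice(10_000, 20_000)
    atten = 20 * np.log10(np.sqrt(np.mean(y[mid] ** 2)) / np.sqrt(np.mean(x[mid] ** 2)))
    assert atten < -30


def test_highpass_rejects_short_signal():
    with pytest.raises(ValueError):
        highpass_filter(np.zeros(10), FS)


# ---------------------------------------------------------------------------
# adaptive noise cancellation

def test_anc_leaves_independent_signals_alone():
    rng = np.random.default_rng(0)
    primary = rng.standard_normal(40_000)
    reference = rng.standard_normal(40_000)
    out = adaptive_noise_cancel(primary, reference)
    tail = slice(10_000, None)
    ratio = np.mean(out[tail] ** 2) / np.mean(primary[tail] ** 2)
    assert 0.9 < ratio < 1.1


def test_anc_removes_shared_mains_tone():
    rng = np.random.default_rng(1)
    t = np.arange(60_000) / FS
    tone = np.sin(2 * np.pi * 50 * t)
    clean = rng.standard_normal(t.size)
    primary = clean + 0.8 * np.sin(2 * np.pi * 50 * t + 0.7)  # delayed copy
    reference = tone + 0.1 * rng.standard_normal(t.size)
    out = adaptive_noise_cancel(primary, reference)

    def peak_50hz(x):
        tail = x[20_000:]
        f = np.fft.rfftfreq(tail.size, 1 / FS)
        p = np.abs(np.fft.rfft(tail)) ** 2
        return p[np.argmin(np.abs(f - 50.0))]

    reduction_db = 10 * np.log10(peak_50hz(primary) / peak_50hz(out))
    assert reduction_db >= 10


def test_anc_reduces_shared_pulse_bursts():
    rng = np.random.default_rng(2)
    n = 50_000
    pulses = np.zeros(n)
    idx = np.arange(20_000, 45_000, 10)
    pulses[idx] = 5.0
    pulses[idx + 1] = -5.0
    primary = rng.standard_normal(n) + 0.7 * pulses
    reference = 0.2 * rng.standard_normal(n) + pulses
    out = adaptive_noise_cancel(primary, reference)
    burst = slice(30_000, 45_000)
    assert np.sqrt(np.mean(out[burst] ** 2)) < np.sqrt(np.mean(primary[burst] ** 2))


def test_anc_zero_variance_reference_warns_and_passes_through():
    primary = np.random.default_rng(3).standard_normal(1000)
    with pytest.warns(UserWarning, match="zero-variance"):
        out = adaptive_noise_cancel(primary, np.zeros(1000))
    np.testing.assert_array_equal(out, primary)


def test_anc_length_mismatch():
    with pytest.raises(ValueError):
        adaptive_noise_cancel(np.zeros(10), np.zeros(11))


# ---------------------------------------------------------------------------
# windowed features

@pytest.mark.parametrize("window, expected", [
    ([0, 0, 0, 0], 0.0),
    ([3, 4], np.sqrt(12.5)),
    ([2.5] * 10, 2.5),
    ([-1.5] * 4, 1.5),
])
def test_rms_examples(window, expected):
    assert rms_feature(np.array(window, dtype=float)) == pytest.approx(expected)


@pytest.mark.parametrize("window, expected", [
    ([5, 5, 5], 0.0),
    ([0, 1, 0, 1], 3.0),
    ([1, 3, 2, 5], 6.0),
])
def test_wl_examples(window, expected):
    assert wl_feature(np.array(window, dtype=float)) == pytest.approx(expected)


def test_feature_errors_on_degenerate_windows():
    with pytest.raises(ValueError):
        rms_feature(np.array([]))
    with pytest.raises(ValueError):
        wl_feature(np.array([1.0]))


@given(st.lists(st.floats(-100, 100), min_size=2, max_size=50))
@settings(deadline=None, max_examples=50)
def test_rms_wl_sign_flip_and_shift_invariances(values):
    w = np.array(values)
    assert rms_feature(-w) == pytest.approx(rms_feature(w))
    assert wl_feature(-w) == pytest.approx(wl_feature(w))
    assert wl_feature(w + 42.0) == pytest.approx(wl_feature(w), abs=1e-9)


def test_extract_features_row_count():
    fs = 1000.0
    channels = {m: np.zeros(10_700) for m in ("cor", "orb", "lev", "zyg", "ris")}
    rows = extract_features(channels, fs)
    assert len(rows) == 10


def test_extract_features_square_wave_closed_form():
    fs = 1000
    square = np.tile([1.0, -1.0], 5 * fs // 2)
    channels = {m: square for m in ("cor", "orb", "lev", "zyg", "ris")}
    rows = extract_features(channels, float(fs))
    assert np.allclose(rows["corrms"], 1.0)
    assert np.allclose(rows["corwl"], 2.0 * (fs - 1))


def test_extract_features_white_noise_calibration():
    rng = np.random.default_rng(4)
    n_windows, fs = 100, 1000
    x = 2.0 * rng.standard_normal(n_windows * fs)
    channels = {m: x for m in ("cor", "orb", "lev", "zyg", "ris")}
    rows = extract_features(channels, float(fs))
    se = 2.0 / np.sqrt(2 * fs * n_windows)
    assert abs(rows["corrms"].mean() - 2.0) < 3 * se


def test_extract_features_time_reversal():
    rng = np.random.default_rng(5)
    fs = 200
    x = rng.standard_normal(6 * fs)
    channels = {m: x for m in ("cor", "orb", "lev", "zyg", "ris")}
    rows = extract_features(channels, float(fs))
    rev = extract_features({m: x[::-1] for m in channels}, float(fs))
    np.testing.assert_allclose(rev["corrms"].to_numpy(), rows["corrms"].to_numpy()[::-1])
    np.testing.assert_allclose(rev["corwl"].to_numpy(), rows["corwl"].to_numpy()[::-1])


# ---------------------------------------------------------------------------
# Hampel filter

def test_hampel_replaces_lone_spike():
    x = np.array([1, 1, 1, 100, 1, 1, 1], dtype=float)
    np.testing.assert_array_equal(hampel_filter(x), np.ones(7))


def test_hampel_keeps_linear_ramp_and_constants():
    ramp = np.arange(1.0, 21.0)
    np.testing.assert_array_equal(hampel_filter(ramp), ramp)
    const = np.full(15, 3.3)
    np.testing.assert_array_equal(hampel_filter(const), const)


def test_hampel_short_series_unchanged():
    x = np.array([5.0, -2.0, 9.0])
    np.testing.assert_array_equal(hampel_filter(x, HampelParams(K=3, t=3.0)), x)


def _hampel_oracle(x, K, t):
    """Brute-force sliding-median reference (truncated windows at the edges)."""
    out = x.copy()
    for i in range(len(x)):
        window = x[max(0, i - K): i + K + 1]
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        if np.abs(x[i] - med) > t * 1.4826 * mad:
            out[i] = med
    return out


@given(st.lists(st.floats(-50, 50), min_size=7, max_size=60),
       st.integers(1, 3), st.sampled_from([2.0, 3.0]))
@settings(deadline=None, max_examples=60)
def test_hampel_matches_bruteforce_oracle(values, K, t):
    x = np.array(values)
    got = hampel_filter(x, HampelParams(K=K, t=t))
    np.testing.assert_allclose(got, _hampel_oracle(x, K, t))


# ---------------------------------------------------------------------------
# standardization

def _rows(values, feature="corrms"):
    from painemg.config import FEATURES
    frame = pd.DataFrame({f: values if f == feature else np.random.default_rng(0).normal(size=len(values))
                          for f in FEATURES})
    return frame


def test_zscore_example_population_sd():
    rows = _rows([2.0, 4.0, 6.0])
    out, stats = zscore_standardize(rows)
    np.testing.assert_allclose(out["corrms"], [-1.22474487, 0.0, 1.22474487])
    assert stats.set_index("feature").loc["corrms", "sigma"] == pytest.approx(np.sqrt(8 / 3))


def test_zscore_idempotent_and_affine_invariant():
    rng = np.random.default_rng(6)
    rows = _rows(rng.normal(size=30))
    once, _ = zscore_standardize(rows)
    twice, _ = zscore_standardize(once)
    np.testing.assert_allclose(twice["corrms"], once["corrms"], atol=1e-12)
    scaled = rows.copy()
    scaled["corrms"] = 3.7 * rows["corrms"] + 11.0
    out_scaled, _ = zscore_standardize(scaled)
    np.testing.assert_allclose(out_scaled["corrms"], once["corrms"], atol=1e-9)


def test_zscore_flat_feature_becomes_zero_with_warning():
    rows = _rows(np.full(10, 4.2))
    with pytest.warns(UserWarning, match="zero variance"):
        out, _ = zscore_standardize(rows)
    assert (out["corrms"] == 0.0).all()


def test_hampel_before_zscore_matters_on_spikes():
    """The chain order (Hampel, then z-score) is observable: reversing it
    changes the output on a spiky series."""
    x = np.ones(40)
    x[20] = 50.0
    rows = _rows(x)
    hampel_then_z, _ = zscore_standardize(
        rows.assign(corrms=hampel_filter(rows["corrms"].to_numpy())))
    z_then_hampel_rows, _ = zscore_standardize(rows)
    z_then_hampel = hampel_filter(z_then_hampel_rows["corrms"].to_numpy())
    assert not np.allclose(hampel_then_z["corrms"].to_numpy(), z_then_hampel)
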