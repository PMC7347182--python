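"""From raw 1000-Hz channels to the ten 1-Hz sEMG features.

The chain, applied per test:

1. zero-phase 20-Hz Butterworth high-pass (movement artifacts, drift),
2. reference-channel adaptive noise cancellation (NLMS against the high-pass
   filtered frontalis channel; removes mains interference and TENS pulse
   artifacts),
3. segmentation into non-overlapping 1-s windows and reduction to root mean
   square (RMS) and waveform length (WL) per muscle,
4. Hampel outlier filtering of each 1-Hz feature series (K = 3, t = 3),
5. per-test z-score standardization (population SD) — exposed here as
   :func:`zscore_standardize` and applied by the pipeline after period
   labelling, because the paper's convention includes exactly the labelled
   no-pain-through-tolerance rows in the statistics.

Feature names are the muscle abbreviation plus the transform: ``corrms``,
``corwl``, ..., ``riswl``.
"""

from __future__ import annotations

import warnings
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal

from .config import FEATURES, MUSCLES, REFERENCE_CHANNEL, HampelParams, PreprocessingConfig
from .cohort import Cohort, RawTest

__all__ = [
    "highpass_filter", "adaptive_noise_cancel", "rms_feature", "wl_feature",
    "extract_features", "hampel_filter", "zscore_standardize",
    "preprocess_test", "preprocess_cohort",
]


def highpass_filter(x: np.ndarray, fs: float, cutoff_hz: float = 20.0,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass (applied forward-backward).

    Raises ``ValueError`` when the signal is shorter than the filter warm-up.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    if len(x) <= 3 * (2 * order + 1):
        raise ValueError(f"signal too short ({len(x)} samples) for the high-pass filter")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


@njit(cache=True)
def _nlms(primary, reference, mu, taps, eps):
    n = primary.shape[0]
    w = np.zeros(taps)
    out = np.empty(n)
    buf = np.zeros(taps)
    for i in range(n):
        # shift reference sample into the delay line
        for j in range(taps - 1, 0, -1):
            buf[j] = buf[j - 1]
        buf[0] = reference[i]
        y = 0.0
        power = eps
        for j in range(taps):
            y += w[j] * buf[j]
            power += buf[j] * buf[j]
        e = primary[i] - y
        g = mu * e / power
        for j in range(taps):
            w[j] += g * buf[j]
        out[i] = e
    return out


def adaptive_noise_cancel(primary: np.ndarray, reference: np.ndarray,
                          step_size: float = 0.1, filter_len: int = 32) -> np.ndarray:
    """Normalized-LMS adaptive noise cancellation.

    Subtracts the adaptively predicted reference-correlated component from
    ``primary``.  The reference should already be high-pass filtered.  A
    zero-variance reference cancels nothing; the primary is returned
    unchanged with a warning.
    """
    primary = np.asarray(primary, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if primary.shape != reference.shape:
        raise ValueError("primary and reference must have equal length")
    ref_var = float(np.var(reference))
    if ref_var == 0.0:
        warnings.warn("zero-variance reference: nothing to cancel", stacklevel=2)
        return primary.copy()
    return _nlms(primary, reference, float(step_size), int(filter_len), 1e-8 * ref_var)


def rms_feature(window: np.ndarray) -> float:
    """Root mean square: sqrt(mean(x_i^2)) over the window."""
    window = np.asarray(window, dtype=np.float64)
    if window.size < 1:
        raise ValueError("RMS requires at least one sample")
    return float(np.sqrt(np.mean(window ** 2)))


def wl_feature(window: np.ndarray) -> float:
    """Waveform length: sum of absolute successive differences."""
    window = np.asarray(window, dtype=np.float64)
    if window.size < 2:
        raise ValueError("WL requires at least two samples")
    return float(np.sum(np.abs(np.diff(window))))


def extract_features(cleaned_channels: Dict[str, np.ndarray], fs: float) -> pd.DataFrame:
    """Reduce each muscle channel to 1-Hz RMS and WL rows.

    Windows are non-overlapping 1-s segments aligned to the recording start;
    a trailing partial window is discarded.  Returns one row per window with
    a ``time_s`` column holding the window-start time.
    """
    nfs = int(round(fs))
    lengths = {len(v) for v in cleaned_channels.values()}
    if len(lengths) != 1:
        raise ValueError("all channels must have equal length")
    n = lengths.pop()
    if n < nfs:
        raise ValueError("need at least one full 1-s window")
    n_windows = n // nfs
    out = {"time_s": np.arange(n_windows, dtype=float)}
    for muscle in MUSCLES:
        x = np.asarray(cleaned_channels[muscle], dtype=np.float64)[: n_windows * nfs]
        win = x.reshape(n_windows, nfs)
        out[f"{muscle}rms"] = np.sqrt(np.mean(win ** 2, axis=1))
        out[f"{muscle}wl"] = np.sum(np.abs(np.diff(win, axis=1)), axis=1)
    return pd.DataFrame(out)


def hampel_filter(series: np.ndarray, params: HampelParams = HampelParams()) -> np.ndarray:
    """Sliding-window Hampel filter.

    A point deviating from its (2K+1)-window median by more than
    ``t * 1.4826 * MAD`` is replaced by that median.  Edge windows are
    truncated to the available samples.  Series shorter than 2K+1 are
    returned unchanged.
    """
    params.validate()
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    K = params.K
    if n < 2 * K + 1:
        return x.copy()
    out = x.copy()
    # interior: full (2K+1)-sample windows, vectorized
    windows = np.lib.stride_tricks.sliding_window_view(x, 2 * K + 1)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    centre = x[K:n - K]
    mask = np.abs(centre - med) > params.t * 1.4826 * mad
    out[K:n - K] = np.where(mask, med, centre)
    # edges: truncated windows
    for i in list(range(K)) + list(range(n - K, n)):
        lo, hi = max(0, i - K), min(n, i + K + 1)
        window = x[lo:hi]
        m = np.median(window)
        sigma = 1.4826 * np.median(np.abs(window - m))
        if np.abs(x[i] - m) > params.t * sigma:
            out[i] = m
    return out


def zscore_standardize(rows: pd.DataFrame, features=FEATURES,
                       ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-test z-transformation (population SD) of one test's feature rows.

    Returns the standardized rows plus a (feature, mu, sigma) frame.  A
    zero-variance feature (flatlined electrode) is set to zero with a
    warning rather than propagating NaNs.
    """
    if len(rows) < 2:
        raise ValueError("standardization needs at least two rows")
    out = rows.copy()
    stats = []
    for feat in features:
        values = rows[feat].to_numpy(dtype=np.float64)
        mu = float(np.mean(values))
        sigma = float(np.std(values))  # population (divide by n)
        if sigma <= 1e-12 * max(abs(mu), 1.0):  # flatlined electrode
            warnings.warn(f"zero variance for feature {feat}; set to 0", stacklevel=2)
            out[feat] = 0.0
        else:
            out[feat] = (values - mu) / sigma
        stats.append({"feature": feat, "mu": mu, "sigma": sigma})
    return out, pd.DataFrame(stats)


def preprocess_test(test: RawTest, config: PreprocessingConfig = PreprocessingConfig(),
                    ) -> pd.DataFrame:
    """Steps 1-4 for one test: filter, cancel, extract, Hampel.

    Returns unstandardized 1-Hz feature rows with subject/test metadata;
    standardization (step 5) is applied after labelling.
    """
    config.validate()
    fs = test.fs
    ref = highpass_filter(test.channels[REFERENCE_CHANNEL], fs,
                          config.highpass_cutoff, config.filter_order)
    cleaned = {}
    for muscle in MUSCLES:
        filtered = highpass_filter(test.channels[muscle], fs,
                                   config.highpass_cutoff, config.filter_order)
        cleaned[muscle] = adaptive_noise_cancel(filtered, ref,
                                                config.anc_step, config.anc_taps)
    rows = extract_features(cleaned, fs)
    for feat in FEATURES:
        rows[feat] = hampel_filter(rows[feat].to_numpy(), config.hampel)
    rows.insert(0, "subject_id", test.subject_id)
    rows.insert(1, "test_id", test.test_id)
    rows.insert(2, "stimulus_type", test.stimulus_type)
    return rows


def preprocess_cohort(cohort: Cohort, config: PreprocessingConfig = PreprocessingConfig(),
                      ) -> pd.DataFrame:
    """Concatenated unstandardized feature rows for every test in the cohort."""
    frames = [preprocess_test(test, config) for test in cohort.tests]
    return pd.concat(frames, ignore_index=True)
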