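"""Synthetic facial-sEMG cohort generation.

Emulates the data structure of a pain-induction study: 31 subjects each
undergo up to four tests (two heat, two electrical), during which six
channels (five facial muscles plus a frontalis noise reference) are recorded
at 1000 Hz together with three event timestamps — stimulus start (t1),
self-reported pain threshold (t2) and pain tolerance (t3).

Each muscle channel is built from two band-limited Gaussian components:

* a resting noise floor occupying a lower-frequency band, and
* a muscle-activity component spanning the full EMG band, scaled by a
  per-second activity envelope that combines the deterministic pain ramp,
  spontaneous expression bursts and (pre-stimulus) talking bursts.

The corrugator ramp rises linearly from t1 to t3; the remaining muscles stay
quiet until the pain threshold t2 and ramp over [t2, t3].  All channels share
mains interference, baseline drift and (for electrical tests) TENS pulse
artifacts that are injected coherently into the frontalis reference so that
adaptive cancellation can remove them.  Sparse high-amplitude motion spikes
are added per channel.

The random stream is split so that event timestamps are identical whether or
not signals are synthesized (``events_only=True`` gives a fast
manifest-only path).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import signal

from .config import (CHANNELS, MUSCLES, REFERENCE_CHANNEL, CohortConfig,
                     ConfigurationError, DurationParams, EnvelopeParams,
                     NoiseParams, run_config_to_dict)

__all__ = [
    "SubjectProfile", "RawTest", "Cohort",
    "sample_test_durations", "synthesize_channels", "generate_cohort",
    "write_cohort", "read_cohort",
]


@dataclass
class SubjectProfile:
    """Per-subject expressiveness: one gain per muscle plus a responder class."""

    subject_id: str
    gains: Dict[str, float]
    responder_class: str           # "expressive" | "low_expressive"
    duration_scale: float = 1.0    # per-subject multiplier on test durations


@dataclass
class RawTest:
    """One test's raw six-channel recording plus its event timestamps."""

    subject_id: str
    test_id: str
    stimulus_type: str             # "heat" | "electrical"
    side: str                      # "left" | "right"
    fs: float
    t1: float
    t2: float
    t3: float
    channels: Dict[str, np.ndarray] = field(default_factory=dict)
    #: synthetic ground truth (per-second activity envelope per muscle);
    #: absent for real data.
    truth: Optional[Dict[str, np.ndarray]] = None

    @property
    def duration(self) -> float:
        return self.t3 - self.t1

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))


@dataclass
class Cohort:
    tests: List[RawTest]
    manifest: pd.DataFrame
    profiles: Dict[str, SubjectProfile]
    config: CohortConfig


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    """Rejection-sample N(mean, sd^2) truncated below at ``floor``."""
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return float(x)
    return float(floor)  # pathological parameters; degenerate but safe


def sample_test_durations(stimulus_type: str, duration_params: Dict[str, DurationParams],
                          rng: np.random.Generator, floor: float = 8.0,
                          scale: float = 1.0) -> tuple[float, float]:
    """Draw (t2 - t1, t3 - t2) for one test.

    Both components are truncated below at ``floor`` seconds so that every
    half-period P1..P4 contains at least two 1-s samples.  ``scale`` is the
    subject-level duration multiplier (applied before truncation).
    """
    try:
        params = duration_params[stimulus_type]
    except KeyError:
        raise ConfigurationError(f"no duration parameters for stimulus {stimulus_type!r}")
    params.validate()
    thr = _truncnorm(rng, scale * params.threshold_mean, scale * params.threshold_sd, floor)
    tol = _truncnorm(rng, scale * params.tolerance_mean, scale * params.tolerance_sd, floor)
    return thr, tol


@functools.lru_cache(maxsize=32)
def _band_sos_and_gain(low: float, high: float, fs: float, order: int = 4):
    """Band-pass SOS plus the factor turning unit-variance white noise into
    unit-variance band-limited noise (average squared magnitude response)."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=4096, fs=fs)
    power = float(np.mean(np.abs(h) ** 2))
    return sos, 1.0 / math.sqrt(power)


def _band_noise(rng: np.random.Generator, n: int, band, fs: float) -> np.ndarray:
    sos, gain = _band_sos_and_gain(band[0], band[1], fs)
    white = rng.standard_normal(n)
    return gain * signal.sosfilt(sos, white)


def _burst_envelope(rng: np.random.Generator, n: int, fs: float, rate: float,
                    dur_mean: float, amp_mean: float,
                    t_start: float, t_stop: float) -> np.ndarray:
    """Sum of half-sine bumps with Poisson onsets in [t_start, t_stop)."""
    env = np.zeros(n)
    span = max(t_stop - t_start, 0.0)
    n_events = rng.poisson(rate * span) if rate > 0 and span > 0 else 0
    if n_events == 0:
        return env
    onsets = t_start + rng.uniform(0.0, span, size=n_events)
    durations = rng.exponential(dur_mean, size=n_events) + 0.3
    amps = rng.exponential(amp_mean, size=n_events)
    for onset, dur, amp in zip(onsets, durations, amps):
        i0 = int(onset * fs)
        i1 = min(int((onset + dur) * fs), n)
        if i1 <= i0:
            continue
        env[i0:i1] += amp * np.sin(np.linspace(0.0, np.pi, i1 - i0))
    return env


def _pain_ramp(t: np.ndarray, muscle: str, t1: float, t2: float, t3: float) -> np.ndarray:
    """Deterministic envelope shape f_m(t) in [0, 1]."""
    if muscle == "cor":
        ramp = (t - t1) / (t3 - t1)
    else:
        ramp = (t - t2) / (t3 - t2)
    return np.clip(ramp, 0.0, None) * (t <= t3)


def synthesize_channels(profile: SubjectProfile, stimulus_type: str,
                        t1: float, t2: float, t3: float,
                        noise: NoiseParams, envelope: EnvelopeParams,
                        fs: float, rng: np.random.Generator,
                        ) -> tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Synthesize all six channels of one test.

    Returns ``(channels, truth)`` where ``truth`` holds each muscle's
    per-second activity envelope (the quantity the 1-Hz features estimate).
    """
    if not t1 < t2 < t3:
        raise ConfigurationError(f"event ordering violated: {(t1, t2, t3)}")
    n = int(math.ceil(t3 + 1.0) * fs)
    t = np.arange(n) / fs
    sigma0 = noise.floor_sigma

    # components shared across channels
    line_phase = rng.uniform(0.0, 2.0 * np.pi)
    line = noise.line_amp * sigma0 * np.sin(2.0 * np.pi * noise.line_freq * t + line_phase)

    pulses = np.zeros(n)
    if stimulus_type == "electrical" and noise.pulse_amp_step > 0:
        # TENS artifact: pulse train whose amplitude steps up every level period
        period = int(round(fs / noise.pulse_freq))
        idx = np.arange(int(t1 * fs), min(int(t3 * fs), n - 1), max(period, 1))
        level = 1.0 + np.floor((idx / fs - t1) / noise.pulse_level_period_s)
        amp = noise.pulse_amp_step * sigma0 * level
        pulses[idx] += amp
        pulses[idx + 1] -= amp     # biphasic blip

    talk_shared = _burst_envelope(rng, n, fs, envelope.talk_rate,
                                  envelope.burst_duration_mean, envelope.talk_amp_mean,
                                  0.0, t1)

    channels: Dict[str, np.ndarray] = {}
    truth: Dict[str, np.ndarray] = {}
    n_seconds = n // int(fs)
    for muscle in MUSCLES:
        floor_noise = sigma0 * _band_noise(rng, n, noise.floor_band, fs)
        act_carrier = _band_noise(rng, n, noise.activity_band, fs)
        gain = profile.gains[muscle]
        act = sigma0 * gain * _pain_ramp(t, muscle, t1, t2, t3)
        act = act + sigma0 * _burst_envelope(
            rng, n, fs, envelope.burst_rate, envelope.burst_duration_mean,
            envelope.burst_amp_mean, 0.0, t3)
        if muscle in envelope.talk_channels:
            act = act + sigma0 * talk_shared * rng.uniform(0.6, 1.2)

        drift = noise.drift_amp * sigma0 * _slow_drift(rng, n, fs)
        spikes = _spike_train(rng, n, fs, noise.spike_rate,
                              noise.spike_amp * sigma0, noise.spike_width_ms)
        line_coupling = rng.uniform(0.7, 1.3)
        pulse_coupling = rng.uniform(0.5, 0.9)
        channels[muscle] = (floor_noise + act * act_carrier + line * line_coupling
                            + drift + spikes + pulse_coupling * pulses
                            ).astype(np.float32)
        per_second = act[: n_seconds * int(fs)].reshape(n_seconds, int(fs)).mean(axis=1)
        truth[muscle] = per_second

    ref_floor = sigma0 * _band_noise(rng, n, noise.floor_band, fs)
    ref_drift = noise.drift_amp * sigma0 * _slow_drift(rng, n, fs)
    channels[REFERENCE_CHANNEL] = (ref_floor + line + ref_drift + pulses).astype(np.float32)
    return channels, truth


def _slow_drift(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Sum of a few sub-hertz sinusoids with random phases, unit peak scale."""
    t = np.arange(n) / fs
    drift = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.05, 0.8)
        drift += rng.uniform(0.2, 0.5) * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return drift


def _spike_train(rng: np.random.Generator, n: int, fs: float, rate: float,
                 amp: float, width_ms: float) -> np.ndarray:
    out = np.zeros(n)
    n_spikes = rng.poisson(rate * n / fs) if rate > 0 else 0
    width = max(int(width_ms * fs / 1000.0), 2)
    window = np.hanning(width)
    for _ in range(n_spikes):
        i0 = rng.integers(0, max(n - width, 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[i0:i0 + width] += sign * amp * rng.uniform(0.7, 1.3) * window[: n - i0]
    return out


def _sample_profiles(config: CohortConfig, rng: np.random.Generator) -> Dict[str, SubjectProfile]:
    env = config.envelope
    mix = config.responder_mix
    profiles = {}
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        subj_mult = rng.lognormal(mean=-0.5 * env.subject_sigma ** 2, sigma=env.subject_sigma)
        low = rng.random() < mix.low_expressive_fraction
        if low:
            subj_mult *= mix.low_expressive_scale
        gains = {}
        for m in MUSCLES:
            jitter = rng.lognormal(mean=-0.5 * env.muscle_jitter_sigma ** 2,
                                   sigma=env.muscle_jitter_sigma)
            gains[m] = env.base_gains[m] * subj_mult * jitter
        dur_scale = rng.lognormal(mean=-0.5 * config.duration_subject_sigma ** 2,
                                  sigma=config.duration_subject_sigma)
        profiles[sid] = SubjectProfile(
            subject_id=sid, gains=gains,
            responder_class="low_expressive" if low else "expressive",
            duration_scale=dur_scale)
    return profiles


_TEST_PLAN = [  # (test index, stimulus, side)
    (1, "heat", "left"), (2, "heat", "right"),
    (3, "electrical", "left"), (4, "electrical", "right"),
]


def generate_cohort(config: CohortConfig, events_only: bool = False) -> Cohort:
    """Generate the full cohort deterministically from ``config.seed``.

    ``events_only=True`` skips signal synthesis but produces the identical
    manifest (timestamps, exclusions, profiles) — the structural and signal
    random streams are independent.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    struct_ss, signal_ss = ss.spawn(2)
    rng = np.random.default_rng(struct_ss)
    profiles = _sample_profiles(config, rng)

    plan = _TEST_PLAN[: config.tests_per_subject]
    records = []
    for sid, profile in profiles.items():
        for idx, stim, side in plan:
            thr, tol = sample_test_durations(
                stim, config.duration_params, rng,
                floor=config.duration_floor_s, scale=profile.duration_scale)
            t1 = config.baseline_lead_s
            records.append(dict(subject_id=sid, test_id=f"{sid}_T{idx}",
                                stimulus_type=stim, side=side,
                                t1=t1, t2=t1 + thr, t3=t1 + thr + tol))

    # exclusions: drawn from the electrical tests (falling back to any test)
    n_excl = config.n_excluded_tests
    elec = [i for i, r in enumerate(records) if r["stimulus_type"] == "electrical"]
    pool = elec if len(elec) >= n_excl else list(range(len(records)))
    excluded = set(rng.choice(pool, size=n_excl, replace=False)) if n_excl else set()
    records = [r for i, r in enumerate(records) if i not in excluded]

    signal_children = signal_ss.spawn(len(records))
    tests: List[RawTest] = []
    for rec, child in zip(records, signal_children):
        test = RawTest(subject_id=rec["subject_id"], test_id=rec["test_id"],
                       stimulus_type=rec["stimulus_type"], side=rec["side"],
                       fs=config.sampling_rate, t1=rec["t1"], t2=rec["t2"], t3=rec["t3"])
        if not events_only:
            chans, truth = synthesize_channels(
                profiles[rec["subject_id"]], rec["stimulus_type"],
                rec["t1"], rec["t2"], rec["t3"],
                config.noise, config.envelope, config.sampling_rate,
                np.random.default_rng(child))
            test.channels = chans
            test.truth = truth
        tests.append(test)

    manifest = pd.DataFrame(
        [dict(subject_id=tst.subject_id, test_id=tst.test_id,
              stimulus_type=tst.stimulus_type, side=tst.side,
              t1=tst.t1, t2=tst.t2, t3=tst.t3) for tst in tests])
    return Cohort(tests=tests, manifest=manifest, profiles=profiles, config=config)


# ---------------------------------------------------------------------------
# file interface: one CSV per test plus a manifest and a config echo

def write_cohort(cohort: Cohort, out_dir) -> Path:
    out = Path(out_dir)
    raw_dir = out / "raw"
    raw_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for test in cohort.tests:
        path = raw_dir / f"{test.test_id}.csv"
        n = test.n_samples
        frame = pd.DataFrame({"time_s": np.arange(n) / test.fs})
        for name in CHANNELS:
            frame[name] = test.channels[name]
        frame.to_csv(path, index=False, float_format="%.5g")
        paths.append(str(path.relative_to(out)))
    manifest = cohort.manifest.copy()
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    import yaml

    from .config import RunConfig
    with open(out / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(run_config_to_dict(RunConfig(cohort=cohort.config))["cohort"],
                       fh, sort_keys=False)
    return out / "manifest.csv"


def read_cohort(manifest_path, fs: Optional[float] = None) -> Cohort:
    """Load raw tests written by :func:`write_cohort` (or real data in the
    same layout)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    tests = []
    for _, row in manifest.iterrows():
        frame = pd.read_csv(base / row["path"])
        dt = float(frame["time_s"].iloc[1] - frame["time_s"].iloc[0])
        rate = fs if fs is not None else 1.0 / dt
        channels = {name: frame[name].to_numpy(dtype=np.float32) for name in CHANNELS}
        tests.append(RawTest(subject_id=row["subject_id"], test_id=row["test_id"],
                             stimulus_type=row["stimulus_type"], side=row["side"],
                             fs=rate, t1=row["t1"], t2=row["t2"], t3=row["t3"],
                             channels=channels))
    cfg = CohortConfig()
    return Cohort(tests=tests, manifest=manifest.drop(columns=["path"]),
                  profiles={}, config=cfg)
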