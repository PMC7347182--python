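"""Configuration objects for the cohort generator, preprocessing chain and model.

Every tunable of the pipeline lives in one of the dataclasses below so that a
run is fully determined by a :class:`RunConfig` plus its seed.  All classes
round-trip through plain dictionaries (and therefore YAML) via
:func:`run_config_to_dict` / :func:`run_config_from_dict`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

MUSCLES: Tuple[str, ...] = ("cor", "orb", "lev", "zyg", "ris")
REFERENCE_CHANNEL = "frontalis_ref"
CHANNELS: Tuple[str, ...] = MUSCLES + (REFERENCE_CHANNEL,)

#: The ten 1-Hz features: each muscle's windowed RMS and waveform length.
FEATURES: Tuple[str, ...] = tuple(f"{m}{kind}" for m in MUSCLES for kind in ("rms", "wl"))

STIMULUS_TYPES: Tuple[str, ...] = ("heat", "electrical")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class DurationParams:
    """Truncated-normal parameters (seconds) for one stimulus type.

    ``threshold_*`` describes the stimulus-start-to-pain-threshold interval
    (t2 - t1) and ``tolerance_*`` the threshold-to-tolerance interval
    (t3 - t2).
    """

    threshold_mean: float
    threshold_sd: float
    tolerance_mean: float
    tolerance_sd: float

    def validate(self) -> None:
        for name in ("threshold_mean", "tolerance_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"DurationParams.{name} must be positive")
        for name in ("threshold_sd", "tolerance_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"DurationParams.{name} must be nonnegative")


@dataclass
class EnvelopeParams:
    """Pain-response envelope shapes and facial-expressiveness population spread.

    ``base_gains`` sets the asymptotic activity amplitude per muscle (relative
    to the resting noise floor) for an average expressive subject; the
    corrugator is strongest, rising from stimulus start, while the other
    muscles stay near baseline until the pain threshold and ramp afterwards.
    Spontaneous expression bursts (pain-independent) and pre-stimulus talking
    bursts are what limit the period information in the features.
    """

    base_gains: Dict[str, float] = field(
        default_factory=lambda: {"cor": 0.85, "orb": 0.36, "lev": 0.42, "zyg": 0.26, "ris": 0.26}
    )
    subject_sigma: float = 0.65        # lognormal sigma of per-subject expressiveness
    muscle_jitter_sigma: float = 0.30  # extra per-subject-per-muscle lognormal jitter
    burst_rate: float = 0.55           # spontaneous bursts per second, per muscle
    burst_duration_mean: float = 1.5   # seconds
    burst_amp_mean: float = 1.5        # relative to the noise floor
    talk_rate: float = 0.25            # talking bursts per second before stimulus start
    talk_amp_mean: float = 1.2
    talk_channels: Tuple[str, ...] = ("lev", "zyg", "ris")

    def validate(self) -> None:
        if set(self.base_gains) != set(MUSCLES):
            raise ConfigurationError("base_gains must cover exactly the five muscles")
        if any(g < 0 for g in self.base_gains.values()):
            raise ConfigurationError("base_gains must be nonnegative")
        for name in ("subject_sigma", "muscle_jitter_sigma", "burst_rate",
                     "burst_duration_mean", "burst_amp_mean", "talk_rate", "talk_amp_mean"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"EnvelopeParams.{name} must be nonnegative")


@dataclass
class ResponderMix:
    """Mixture of expressive and low-expressive subjects."""

    low_expressive_fraction: float = 0.2
    low_expressive_scale: float = 0.25

    def validate(self) -> None:
        if not 0.0 <= self.low_expressive_fraction <= 1.0:
            raise ConfigurationError("low_expressive_fraction must be in [0, 1]")
        if not 0.0 <= self.low_expressive_scale <= 1.0:
            raise ConfigurationError("low_expressive_scale must be in [0, 1]")


@dataclass
class NoiseParams:
    """Amplitudes of the nuisance components added to every recording.

    All amplitudes are relative to ``floor_sigma``, the RMS of the resting
    noise floor.  The floor occupies a narrower band than the muscle-activity
    component: resting baseline in facial sEMG is dominated by lower-frequency
    content, whereas recruited muscle activity carries power across the full
    EMG band.
    """

    floor_sigma: float = 1.0
    floor_band: Tuple[float, float] = (20.0, 90.0)
    activity_band: Tuple[float, float] = (20.0, 450.0)
    line_freq: float = 50.0       # mains interference
    line_amp: float = 1.5
    drift_amp: float = 3.0        # slow baseline wander, removed by the high-pass
    spike_rate: float = 0.02      # motion-artifact spikes per second per channel
    spike_amp: float = 10.0
    spike_width_ms: float = 20.0
    pulse_amp_step: float = 0.4   # TENS artifact amplitude increment per level
    pulse_freq: float = 100.0     # TENS pulse repetition rate
    pulse_level_period_s: float = 3.0

    def validate(self) -> None:
        if self.floor_sigma <= 0:
            raise ConfigurationError("floor_sigma must be positive")
        for band in (self.floor_band, self.activity_band):
            if not 0 < band[0] < band[1]:
                raise ConfigurationError(f"invalid frequency band {band}")
        for name in ("line_amp", "drift_amp", "spike_rate", "spike_amp",
                     "spike_width_ms", "pulse_amp_step", "pulse_freq",
                     "pulse_level_period_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"NoiseParams.{name} must be nonnegative")


def _default_duration_params() -> Dict[str, DurationParams]:
    # Chosen so that the 120-test cohort's (t3 - t1) has mean ~110 s, SD ~42 s,
    # with heat tests showing the longer threshold period.
    return {
        "heat": DurationParams(75.0, 25.0, 46.5, 20.0),
        "electrical": DurationParams(52.5, 18.0, 43.5, 18.0),
    }


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort, including the seed."""

    n_subjects: int = 31
    tests_per_subject: int = 4           # heat x2 (left/right), electrical x2
    n_excluded_tests: int = 4
    sampling_rate: float = 1000.0
    baseline_lead_s: float = 32.0        # pre-stimulus recording; must be >= 30
    duration_params: Dict[str, DurationParams] = field(default_factory=_default_duration_params)
    duration_floor_s: float = 8.0
    duration_subject_sigma: float = 0.25  # lognormal spread of per-subject test length
    envelope: EnvelopeParams = field(default_factory=EnvelopeParams)
    responder_mix: ResponderMix = field(default_factory=ResponderMix)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.tests_per_subject < 1:
            raise ConfigurationError("n_subjects and tests_per_subject must be >= 1")
        if self.n_excluded_tests < 0:
            raise ConfigurationError("n_excluded_tests must be >= 0")
        if self.n_excluded_tests >= self.n_subjects * self.tests_per_subject:
            raise ConfigurationError("cannot exclude every test")
        if self.baseline_lead_s < 30.0:
            raise ConfigurationError("baseline_lead_s must be >= 30 s (period P0 needs 30 s)")
        if self.duration_floor_s <= 0:
            raise ConfigurationError("duration_floor_s must be positive")
        for params in self.duration_params.values():
            params.validate()
        self.envelope.validate()
        self.responder_mix.validate()
        self.noise.validate()
        nyquist = self.sampling_rate / 2.0
        if self.noise.line_freq >= nyquist or self.noise.activity_band[1] >= nyquist:
            raise ConfigurationError(
                "sampling_rate must exceed twice the highest deterministic frequency"
            )


@dataclass
class HampelParams:
    """Half-window K (samples) and threshold t (robust SDs) of the Hampel filter."""

    K: int = 3
    t: float = 3.0

    def validate(self) -> None:
        if self.K < 1:
            raise ConfigurationError("Hampel K must be >= 1")
        if self.t <= 0:
            raise ConfigurationError("Hampel t must be positive")


@dataclass
class PreprocessingConfig:
    highpass_cutoff: float = 20.0
    filter_order: int = 4
    anc_step: float = 0.1
    anc_taps: int = 32
    hampel: HampelParams = field(default_factory=HampelParams)

    def validate(self) -> None:
        if self.highpass_cutoff <= 0 or self.filter_order < 1:
            raise ConfigurationError("invalid high-pass settings")
        if not 0 < self.anc_step <= 2 or self.anc_taps < 1:
            raise ConfigurationError("invalid adaptive-canceller settings")
        self.hampel.validate()


@dataclass
class ModelConfig:
    """kNN ordinal-model settings: candidate features, k grid and permutations."""

    candidate_features: Tuple[str, ...] = ("corrms", "corwl", "levwl", "orbwl")
    k_grid: Tuple[int, ...] = tuple(range(1, 32, 2))
    distance: str = "euclidean"
    n_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not self.candidate_features:
            raise ConfigurationError("candidate_features must be non-empty")
        unknown = set(self.candidate_features) - set(FEATURES)
        if unknown:
            raise ConfigurationError(f"unknown features: {sorted(unknown)}")
        if any(k < 1 for k in self.k_grid) or not self.k_grid:
            raise ConfigurationError("k_grid must contain integers >= 1")
        if self.distance != "euclidean":
            raise ConfigurationError("only the Euclidean distance is supported")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def validate(self) -> None:
        self.cohort.validate()
        self.preprocessing.validate()
        self.model.validate()


# ---------------------------------------------------------------------------
# dict / YAML round-tripping

def run_config_to_dict(config: RunConfig) -> dict:
    return asdict(config)


def _duration_params_from(d: dict) -> Dict[str, DurationParams]:
    return {k: DurationParams(**v) for k, v in d.items()}


def run_config_from_dict(d: dict) -> RunConfig:
    cohort = dict(d.get("cohort", {}))
    if "duration_params" in cohort:
        cohort["duration_params"] = _duration_params_from(cohort["duration_params"])
    for key, cls in (("envelope", EnvelopeParams), ("responder_mix", ResponderMix),
                     ("noise", NoiseParams)):
        if key in cohort:
            sub = dict(cohort[key])
            for tup_key in ("floor_band", "activity_band", "talk_channels"):
                if tup_key in sub:
                    sub[tup_key] = tuple(sub[tup_key])
            cohort[key] = cls(**sub)
    pre = dict(d.get("preprocessing", {}))
    if "hampel" in pre:
        pre["hampel"] = HampelParams(**pre["hampel"])
    model = dict(d.get("model", {}))
    for tup_key in ("candidate_features", "k_grid"):
        if tup_key in model:
            model[tup_key] = tuple(model[tup_key])
    return RunConfig(
        cohort=CohortConfig(**cohort),
        preprocessing=PreprocessingConfig(**pre),
        model=ModelConfig(**model),
    )


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(run_config_to_dict(config), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))
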