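"""Configuration objects for the synthetic oddball protocol and pipeline.

Defaults encode the study conditions the generator emulates: 3 runs of 125
visual stimuli (80 % standard / 20 % target, the first two always standard),
200 ms stimulus duration, inter-trial interval uniform on [2, 3] s, a 98.4 %
hit rate with 397.2 +/- 38.9 ms response times, and blinks following 46 % of
standard and 48 % of target stimuli.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .channels import DEFAULT_CHANNELS


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Blink latency anchoring presets. Under ``stimulus_anchored`` blinks after
#: both stimulus classes are timed from stimulus onset (means 595 / 779 ms);
#: under ``response_anchored`` target-trial blinks are timed from the trial's
#: button press (mean 511 ms) while standard-trial blinks remain
#: stimulus-timed.
LATENCY_PRESETS = ("stimulus_anchored", "response_anchored")


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and composition of the visual oddball protocol."""

    n_runs: int = 3
    n_stimuli_per_run: int = 125
    target_fraction: float = 0.20
    stim_duration_ms: float = 200.0
    iti_range_ms: tuple[float, float] = (2000.0, 3000.0)
    n_leading_standards: int = 2
    sampling_rate_hz: float = 250.0
    n_channels: int = 34
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    #: silent tail appended after the last stimulus so late epochs fit
    tail_ms: float = 2500.0

    def __post_init__(self):
        if self.n_stimuli_per_run < 0 or self.n_runs < 0:
            raise ConfigurationError("counts must be non-negative")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ConfigurationError("target_fraction must lie in [0, 1]")
        n_targets = self.target_fraction * self.n_stimuli_per_run
        if self.n_stimuli_per_run and abs(n_targets - round(n_targets)) > 1e-9:
            raise ConfigurationError(
                f"target_fraction * n_stimuli_per_run = {n_targets} "
                "is not an integer")
        lo, hi = self.iti_range_ms
        if lo > hi or lo < 0:
            raise ConfigurationError("invalid ITI range")
        if self.n_stimuli_per_run and \
                self.n_leading_standards >= self.n_stimuli_per_run:
            raise ConfigurationError(
                "n_leading_standards must be < n_stimuli_per_run")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be positive")
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError(
                f"{self.n_channels} channels requested but "
                f"{len(self.channel_names)} names given")

    @property
    def n_targets_per_run(self) -> int:
        return round(self.target_fraction * self.n_stimuli_per_run)


@dataclass(frozen=True)
class BehaviourConfig:
    """Behavioural response and blink-timing model.

    Blink latencies are drawn from a Gamma distribution with the configured
    mean and coefficient of variation (positive support, right-skewed, as
    observed in blink-latency histograms).
    """

    hit_rate: float = 0.984
    rt_mean_ms: float = 397.2
    rt_sd_ms: float = 38.9
    blink_prob_standard: float = 0.46
    blink_prob_target: float = 0.48
    latency_preset: str = "stimulus_anchored"
    blink_latency_mean_standard_ms: float = 595.0
    blink_latency_mean_target_ms: float = 779.0
    blink_latency_mean_from_response_ms: float = 511.0
    blink_latency_cv: float = 0.30
    blink_refractory_ms: float = 250.0
    #: rate (per second of ITI slack) of task-unrelated background blinks
    background_blink_rate_hz: float = 0.0

    def __post_init__(self):
        for name in ("hit_rate", "blink_prob_standard", "blink_prob_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.latency_preset not in LATENCY_PRESETS:
            raise ConfigurationError(
                f"latency_preset must be one of {LATENCY_PRESETS}")
        for name in ("rt_mean_ms", "blink_latency_mean_standard_ms",
                     "blink_latency_mean_target_ms",
                     "blink_latency_mean_from_response_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.rt_sd_ms < 0 or self.blink_latency_cv < 0:
            raise ConfigurationError("dispersions must be non-negative")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive background noise: 1/f ("pink") EEG noise plus sensor noise.

    With ``spatial_structure="dipolar"`` (the default) the 1/f background is
    generated by random intracranial dipolar sources projected through the
    head model, giving the spatially correlated background of real EEG;
    ``"independent"`` gives channel-wise independent pink noise.
    ``pink_rms_uv`` is the mean per-channel RMS in either case.
    """

    pink_exponent: float = 1.0
    pink_rms_uv: float = 5.0
    sensor_white_rms_uv: float = 1.0
    alpha_band: Optional[dict] = None  # {"center_hz": float, "rms_uv": float}
    spatial_structure: str = "dipolar"
    n_background_sources: int = 40

    def __post_init__(self):
        if self.pink_rms_uv < 0 or self.sensor_white_rms_uv < 0:
            raise ConfigurationError("noise RMS values must be >= 0")
        if self.alpha_band is not None and self.alpha_band.get("rms_uv", 0) < 0:
            raise ConfigurationError("alpha_band rms_uv must be >= 0")
        if self.spatial_structure not in ("dipolar", "independent"):
            raise ConfigurationError(
                "spatial_structure must be 'dipolar' or 'independent'")
        if self.n_background_sources < 1:
            raise ConfigurationError("n_background_sources must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration of an end-to-end run."""

    n_subjects: int = 17
    master_seed: int = 0
    alpha: float = 0.05
    roi_label: str = "precuneus"
    analysis_channel: str = "Pz"
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    behaviour: BehaviourConfig = field(default_factory=BehaviourConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    ica_per_run: bool = False
    #: samples the ICA unmixing fit may use after decimation; the group
    #: analysis benefits from more than the blink-extraction minimum
    ica_fit_samples: int = 40000
    align_before_test: bool = True

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    """Serialize any config dataclass to a plain JSON/YAML-safe dict."""
    return _to_plain(cfg)


def _tupled(d: dict, keys) -> dict:
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def pipeline_config_from_dict(doc: dict) -> PipelineConfig:
    doc = dict(doc)
    protocol = ProtocolConfig(**_tupled(doc.pop("protocol", {}),
                                        ("iti_range_ms", "channel_names")))
    behaviour = BehaviourConfig(**doc.pop("behaviour", {}))
    noise = NoiseConfig(**doc.pop("noise", {}))
    return PipelineConfig(protocol=protocol, behaviour=behaviour,
                          noise=noise, **doc)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML or JSON document."""
    import yaml

    text = Path(path).read_text()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") \
        else json.loads(text)
    return pipeline_config_from_dict(doc or {})
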