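"""Pipeline configuration: nested defaults, YAML loading, strict validation.

Every tunable of the pipeline lives here with the default stated in the
module that owns it; a YAML file may override any subset, and unknown keys
are rejected by name rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .denoise import SubtractionParams

__all__ = ["PipelineConfig", "load_config", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass
class EndpointConfig:
    high_frac: float = 0.25  # high energy threshold, fraction of max frame energy
    low_frac: float = 0.05
    zcr_factor: float = 1.5  # multiple of the leading-frame mean ZCR
    min_frames: int = 3


@dataclass
class PreprocessConfig:
    rate: int = 8000
    frame_length: int = 256
    frame_shift: int = 128
    energy_threshold: float = 40.0
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)


@dataclass
class DenoiseConfig:
    alpha: float = 2.0
    beta: float = 0.01
    epsilon: float = 1.47
    alpha_d: float = 0.85
    fft_size: int = 256
    min_track_window: int = 40
    snr_threshold: float = 5.0
    p_smooth: float = 0.9

    def params(self) -> SubtractionParams:
        return SubtractionParams(
            alpha=self.alpha,
            beta=self.beta,
            epsilon=self.epsilon,
            alpha_d=self.alpha_d,
            min_track_window=self.min_track_window,
            snr_threshold=self.snr_threshold,
            p_smooth=self.p_smooth,
        )


@dataclass
class FeaturesConfig:
    n_mels: int = 24
    n_mfcc: int = 12
    f_low: float = 0.0
    f_high: float = 4000.0
    delta_mode: str = "difference"  # or "regression"


@dataclass
class WSVDDConfig:
    C: float = 1.0
    sigma: float | None = None  # None -> median-distance heuristic
    weighted: bool = True
    radius_mode: str = "min_max"


@dataclass
class MultiConfig:
    vote_priority: tuple = ("cough", "scream", "other", "unknown")
    seed: int = 0


@dataclass
class SynthConfig:
    snr_db: float = 15.0
    noise_kind: str = "white"
    seed: int = 0


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    wsvdd: WSVDDConfig = field(default_factory=WSVDDConfig)
    multisvdd: MultiConfig = field(default_factory=MultiConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)


def _apply(obj, overrides: dict, path: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in fields:
            raise ConfigError(f"unknown configuration key: {where}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"{where} must be a mapping")
            _apply(current, value, where)
        else:
            setattr(obj, key, value)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a validated config: YAML overrides on top of the defaults.

    ``path=None`` (or an empty file) yields the all-defaults configuration.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return cfg
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    _apply(cfg, data, "")
    return cfg
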