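"""Study and pipeline configuration objects with YAML (de)serialisation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .design import POSTURES, SENSORS


class ConfigError(ValueError):
    """Raised for invalid study or pipeline configuration."""


def _default_sensor_gains() -> dict[str, float]:
    # Pelvis couples most strongly to whole-body sway (closest to the
    # centre of mass); lower legs next (ankle strategy), trunk/shoulders
    # and upper legs less so.
    return {
        "pelvis": 1.0,
        "T8": 0.75,
        "shoulder_L": 0.6,
        "shoulder_R": 0.6,
        "upper_leg_L": 0.5,
        "upper_leg_R": 0.5,
        "lower_leg_L": 0.8,
        "lower_leg_R": 0.8,
    }


@dataclass
class EffectParams:
    """Effect sizes and noise scales of the synthetic study generator.

    All factor effects act additively on the log of a latent instability
    intensity; the exponentiated latent scales both the amplitude and
    (through ``freq_slope``) the bandwidth of the simulated sway.

    Defaults encode a strong posture (WP) effect, a strong load (LC)
    effect, and a deliberately small surface (SS) effect, so that
    detection power is high for WP/LC and marginal for SS.
    """

    baseline_log_sway: float = -3.0
    beta_wp: tuple[float, ...] = (0.0, 0.1, 0.35, 0.5, 0.65, 0.8)
    beta_ss: float = 0.05
    beta_lc: float = 0.6
    #: posture-specific extra effect when carrying the 10 kg load (WPxLC).
    beta_wp_lc: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.2, 0.3)
    #: posture-specific extra effect on the inclined surface (WPxSS).
    beta_wp_ss: tuple[float, ...] = (0.0,) * 6
    beta_ss_lc: float = 0.0
    beta_ss_lc_wp: tuple[float, ...] = (0.0,) * 6
    subject_sd: float = 0.3
    trial_sd: float = 0.4
    sensor_gains: dict[str, float] = field(default_factory=_default_sensor_gains)
    #: SD (log scale) of per-channel coupling jitter: each sensor axis's
    #: amplitude is multiplied by an independent lognormal factor per
    #: trial, emulating placement/strategy-dependent coupling variation.
    gain_jitter_sd: float = 0.45
    #: passband of the simulated sway process, Hz.
    sway_band: tuple[float, float] = (0.1, 3.0)
    #: exponent coupling the upper passband edge to the latent intensity.
    freq_slope: float = 0.7
    #: COP amplitude (mm) per unit latent instability.
    cop_gain: float = 80.0
    pps_slope: float = 3.0
    pps_intercept: float = 12.0
    pps_noise_sd: float = 0.6

    def __post_init__(self) -> None:
        self.beta_wp = tuple(float(b) for b in self.beta_wp)
        self.beta_wp_lc = tuple(float(b) for b in self.beta_wp_lc)
        self.beta_wp_ss = tuple(float(b) for b in self.beta_wp_ss)
        self.beta_ss_lc_wp = tuple(float(b) for b in self.beta_ss_lc_wp)
        for name in ("beta_wp", "beta_wp_lc", "beta_wp_ss", "beta_ss_lc_wp"):
            if len(getattr(self, name)) != len(POSTURES):
                raise ConfigError(f"{name} must have {len(POSTURES)} entries")
        if any(g < 0 for g in self.sensor_gains.values()):
            raise ConfigError("sensor_gains must be nonnegative")
        lo, hi = self.sway_band
        if not 0 < lo < hi:
            raise ConfigError("sway_band must satisfy 0 < low < high")

    @classmethod
    def null(cls, **overrides: Any) -> "EffectParams":
        """All factor effects zero (for calibration studies)."""
        zeros = dict(
            beta_wp=(0.0,) * 6,
            beta_ss=0.0,
            beta_lc=0.0,
            beta_wp_lc=(0.0,) * 6,
            beta_wp_ss=(0.0,) * 6,
            beta_ss_lc=0.0,
            beta_ss_lc_wp=(0.0,) * 6,
            freq_slope=0.0,
        )
        zeros.update(overrides)
        return cls(**zeros)


@dataclass
class StudyConfig:
    """Size, rates and effect parameters of one synthetic study."""

    n_subjects: int = 30
    n_repetitions: int = 2
    trial_duration: float = 10.0
    acc_rate: float = 240.0
    cop_rate: float = 40.0
    sensor_set: tuple[str, ...] = SENSORS
    effect_params: EffectParams = field(default_factory=EffectParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sensor_set = tuple(self.sensor_set)
        if self.n_subjects < 1 or self.n_repetitions < 1:
            raise ConfigError("n_subjects and n_repetitions must be >= 1")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be positive")
        if self.acc_rate <= 0 or self.cop_rate <= 0:
            raise ConfigError("sampling rates must be positive")
        unknown = set(self.sensor_set) - set(SENSORS)
        if unknown:
            raise ConfigError(f"unknown sensors: {sorted(unknown)}")
        if not self.sensor_set:
            raise ConfigError("sensor_set must not be empty")
        missing = set(self.sensor_set) - set(self.effect_params.sensor_gains)
        if missing:
            raise ConfigError(f"sensor_gains missing for: {sorted(missing)}")
        lo, hi = self.effect_params.sway_band
        if hi >= min(self.acc_rate, self.cop_rate) / 2:
            raise ConfigError("sway_band must lie below the Nyquist frequency")

    @property
    def n_acc_samples(self) -> int:
        return int(round(self.trial_duration * self.acc_rate))

    @property
    def n_cop_samples(self) -> int:
        return int(round(self.trial_duration * self.cop_rate))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: study, preprocessing, stats, ML."""

    study: StudyConfig = field(default_factory=StudyConfig)
    cutoff_acc: float = 10.0
    cutoff_cop: float = 10.0
    filter_order: int = 4
    alpha: float = 0.05
    sensor_configs: tuple[str, ...] = ("SC1", "SC2", "SC3")
    feature_sets: tuple[str, ...] = ("FS1", "FS2", "FS3")
    classifiers: tuple[str, ...] = ()  # empty = full roster
    criterion: str = "pps"
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.criterion not in ("pps", "copv_ap"):
            raise ConfigError("criterion must be 'pps' or 'copv_ap'")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def study_config_to_dict(cfg: StudyConfig) -> dict[str, Any]:
    return _to_plain(cfg)


def study_config_from_dict(d: Mapping[str, Any]) -> StudyConfig:
    d = dict(d)
    ep = d.get("effect_params", {})
    if isinstance(ep, Mapping):
        ep = dict(ep)
        if "sway_band" in ep:
            ep["sway_band"] = tuple(ep["sway_band"])
        d["effect_params"] = EffectParams(**ep)
    if "sensor_set" in d:
        d["sensor_set"] = tuple(d["sensor_set"])
    return StudyConfig(**d)


def load_study_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "study" in raw:  # tolerate a full pipeline file
        raw = raw["study"]
    try:
        return study_config_from_dict(raw)
    except TypeError as exc:
        raise ConfigError(f"bad study config {path}: {exc}") from exc


def save_study_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(study_config_to_dict(cfg), fh, sort_keys=False)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    study = study_config_from_dict(raw.pop("study", {}))
    for key in ("sensor_configs", "feature_sets", "classifiers"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return PipelineConfig(study=study, **raw)
    except TypeError as exc:
        raise ConfigError(f"bad pipeline config {path}: {exc}") from exc
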