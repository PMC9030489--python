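"""Synthetic factorial balance-study generator.

Generates a complete within-subject study — per-sensor tri-axial
acceleration, a two-dimensional COP trajectory and a subjective 0-10
stability rating per trial — whose statistical structure mirrors a
6 (posture) x 2 (surface) x 2 (load) load-holding experiment.

All three outputs are driven by one latent instability intensity per
trial: a log-linear factorial predictor with a between-subject random
effect and residual trial noise, exponentiated to a positive scale. The
sway signals are stationary band-limited Gaussian noise whose sample SD
is proportional to the latent intensity and whose upper passband edge
grows with it, so both amplitude- and frequency-domain sway measures
respond to the injected factor effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .config import ConfigError, EffectParams, StudyConfig
from .design import Condition, enumerate_conditions

__all__ = [
    "TrialRecording",
    "StudyDataset",
    "latent_instability",
    "band_limited_noise",
    "simulate_trial",
    "simulate_study",
]


@dataclass
class TrialRecording:
    """One task execution: signals, rating and condition metadata."""

    subject_id: int
    condition: Condition
    repetition: int
    #: per-sensor acceleration, shape (n_samples, 3), columns AP, ML, IS (m/s^2).
    acc: dict[str, np.ndarray]
    #: COP trajectory, shape (n_samples, 2), columns AP, ML (mm).
    cop: np.ndarray
    #: perceived postural stability rating in [0, 10].
    pps: float
    acc_rate: float
    cop_rate: float
    #: latent instability intensity the trial was generated from.
    latent: float = float("nan")


@dataclass
class StudyDataset:
    """Long-format collection of trials over subjects x conditions x reps."""

    trials: list[TrialRecording]
    config: StudyConfig

    def __len__(self) -> int:
        return len(self.trials)

    def metadata(self):
        """Per-trial metadata table (subject, condition, repetition, pps)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "subject": [t.subject_id for t in self.trials],
                "posture": [t.condition.posture for t in self.trials],
                "surface": [t.condition.surface for t in self.trials],
                "load": [t.condition.load for t in self.trials],
                "repetition": [t.repetition for t in self.trials],
                "pps": [t.pps for t in self.trials],
            }
        )


def log_latent_predictor(
    cond: Condition, subject_effect: float, params: EffectParams
) -> float:
    """Deterministic part of the log latent instability for one trial."""
    j = cond.posture_index
    inc = float(cond.inclined)
    load = float(cond.loaded)
    return (
        params.baseline_log_sway
        + params.beta_wp[j]
        + params.beta_ss * inc
        + params.beta_lc * load
        + params.beta_wp_lc[j] * load
        + params.beta_wp_ss[j] * inc
        + params.beta_ss_lc * inc * load
        + params.beta_ss_lc_wp[j] * inc * load
        + subject_effect
    )


def latent_instability(
    cond: Condition,
    subject_effect: float,
    params: EffectParams,
    rng: np.random.Generator,
) -> float:
    """Draw one trial's positive latent instability intensity.

    exp(baseline + factor effects + interactions + subject effect +
    N(0, trial_sd)); strictly positive by construction.
    """
    eta = log_latent_predictor(cond, subject_effect, params)
    if params.trial_sd > 0:
        eta += rng.normal(0.0, params.trial_sd)
    return math.exp(eta)


def band_limited_noise(
    rng: np.random.Generator,
    n: int,
    rate: float,
    band: tuple[float, float],
    target_sd: float,
    shape: tuple[int, ...] = (),
) -> np.ndarray:
    """White Gaussian noise band-passed to ``band`` and rescaled.

    Each output channel is normalised to have sample SD exactly
    ``target_sd`` and sample mean zero. ``shape`` adds trailing channel
    dimensions, e.g. ``(3,)`` for a tri-axial signal of shape (n, 3).
    """
    lo, hi = band
    nyq = rate / 2
    if not 0 < lo < hi < nyq:
        raise ConfigError(f"band {band} outside (0, {nyq}) Hz")
    white = rng.standard_normal((n, *shape))
    if target_sd == 0:
        return np.zeros_like(white)
    # Filter in the frequency domain: exact second-order Butterworth
    # band-pass magnitude, no start-up transients (a time-domain IIR pass
    # would need ~1/lo seconds of padding, comparable to the whole trial).
    g, sd_theory = _bandpass_gain(n, float(rate), float(lo), float(hi))
    spec = np.fft.rfft(white, axis=0)
    gain = g.reshape((-1,) + (1,) * len(shape))
    x = np.fft.irfft(spec * gain, n=n, axis=0)
    x = x - x.mean(axis=0)
    return x * (target_sd / sd_theory)


@lru_cache(maxsize=256)
def _bandpass_gain(n: int, rate: float, lo: float, hi: float):
    """Band-pass magnitude at the rfft frequencies, plus the analytic
    output SD for unit-variance white input (Parseval over rfft bins),
    so the sample SD equals the target in expectation."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    _, h = sps.sosfreqz(sos, worN=freqs, fs=rate)
    g = np.abs(h)
    weights = np.full(g.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    sd_theory = math.sqrt(float(weights @ g**2) / n)
    return g, sd_theory


def _effective_band(
    params: EffectParams, latent: float, rate: float
) -> tuple[float, float]:
    """Sway passband for a trial: the upper edge grows with instability."""
    lo, hi = params.sway_band
    if params.freq_slope != 0.0:
        factor = (latent / math.exp(params.baseline_log_sway)) ** params.freq_slope
        hi = hi * factor
    hi = float(np.clip(hi, lo * 1.2, 0.95 * rate / 2))
    return lo, hi


def _trial_rng(
    config: StudyConfig, subject_id: int, cond: Condition, repetition: int
) -> np.random.Generator:
    conds = enumerate_conditions()
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed), 1, int(subject_id), conds.index(cond), int(repetition)]
        )
    )


def subject_random_effect(config: StudyConfig, subject_id: int) -> float:
    """Between-subject random intercept, deterministic in (seed, subject)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0, int(subject_id)])
    )
    return float(rng.normal(0.0, config.effect_params.subject_sd))


def simulate_trial(
    subject_id: int,
    cond: Condition,
    repetition: int,
    params: EffectParams,
    config: StudyConfig,
    rng: np.random.Generator | None = None,
    subject_effect: float | None = None,
    round_pps: bool = False,
) -> TrialRecording:
    """Simulate one trial's acceleration, COP and rating.

    Randomness comes from ``rng``; when omitted, a generator seeded
    deterministically from (config.seed, subject, condition, repetition)
    is used, so repeated calls are bit-identical.
    """
    if rng is None:
        rng = _trial_rng(config, subject_id, cond, repetition)
    if subject_effect is None:
        subject_effect = subject_random_effect(config, subject_id)

    latent = latent_instability(cond, subject_effect, params, rng)

    n_acc = config.n_acc_samples
    acc_band = _effective_band(params, latent, config.acc_rate)
    acc: dict[str, np.ndarray] = {}
    for sensor in config.sensor_set:
        gain = params.sensor_gains[sensor]
        x = band_limited_noise(
            rng, n_acc, config.acc_rate, acc_band, gain * latent, shape=(3,)
        )
        if params.gain_jitter_sd > 0 and gain > 0:
            x = x * np.exp(rng.normal(0.0, params.gain_jitter_sd, 3))
        acc[sensor] = x

    cop_band = _effective_band(params, latent, config.cop_rate)
    cop = band_limited_noise(
        rng,
        config.n_cop_samples,
        config.cop_rate,
        cop_band,
        params.cop_gain * latent,
        shape=(2,),
    )

    pps = params.pps_intercept + params.pps_slope * math.log(latent)
    if params.pps_noise_sd > 0:
        pps += rng.normal(0.0, params.pps_noise_sd)
    pps = float(np.clip(pps, 0.0, 10.0))
    if round_pps:
        pps = float(round(pps))

    return TrialRecording(
        subject_id=subject_id,
        condition=cond,
        repetition=repetition,
        acc=acc,
        cop=cop,
        pps=pps,
        acc_rate=config.acc_rate,
        cop_rate=config.cop_rate,
        latent=float(latent),
    )


def simulate_study(config: StudyConfig, round_pps: bool = False) -> StudyDataset:
    """Simulate the full factorial study described by ``config``.

    Every (subject, condition, repetition) cell appears exactly once:
    n_subjects x 24 x n_repetitions trials, deterministic given the seed.
    """
    conditions = enumerate_conditions()
    trials: list[TrialRecording] = []
    for subject in range(1, config.n_subjects + 1):
        s_eff = subject_random_effect(config, subject)
        for cond in conditions:
            for rep in range(1, config.n_repetitions + 1):
                trials.append(
                    simulate_trial(
                        subject,
                        cond,
                        rep,
                        config.effect_params,
                        config,
                        subject_effect=s_eff,
                        round_pps=round_pps,
                    )
                )
    return StudyDataset(trials=trials, config=config)
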