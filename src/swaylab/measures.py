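"""The 43 accelerometer-based postural-stability measures.

The registry expands twelve measure families across their applicable
directions (AP, ML, IS, 2DR, 3DR):

==========  ====================================================  =====
family      meaning                                               count
==========  ====================================================  =====
AVG         mean of |detrended signal| (axes) / mean resultant      5
RNG         range (max - min) of the series                         5
RMS         root mean square of the detrended series                5
ARE         sway area per unit time: SW (triangle sweep),
            CC (95% confidence circle), CE (95% conf. ellipse)      3
FD          fractal dimension from the CC / CE diameter             2
LEN         total trajectory length (AP, ML, 2DR, 3DR)              4
MD          mean distance from the trajectory centre                4
MF          power-spectral mean frequency                           4
MV          mean magnitude of the integrated (velocity) signal      4
PD          planar deviation of displacement / velocity             2
PP          sagittal phase-plane parameter                          1
RMSD        RMS distance from the trajectory centre                 4
==========  ====================================================  =====

Planar statistics (ARE, FD, PD, PP) follow the classical stabilometry
definitions of the confidence-circle/ellipse and phase-plane family,
applied to the acceleration statokinesigram (AP vs. ML) rather than a
COP trajectory. Accelerations stay in m/s^2 throughout; areas are in
(input unit)^2 per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate as spi
from scipy import signal as sps
from scipy import stats as spst

from .preprocessing import DirectionalSignals, preprocess_acc, preprocess_cop
from .simulate import StudyDataset, TrialRecording

_AXES5 = ("AP", "ML", "IS", "2DR", "3DR")
_AXES4 = ("AP", "ML", "2DR", "3DR")

#: The 43 measure names, grouped by family, in canonical order.
MEASURE_NAMES: tuple[str, ...] = (
    *(f"AVG_{d}" for d in _AXES5),
    *(f"RNG_{d}" for d in _AXES5),
    *(f"RMS_{d}" for d in _AXES5),
    "ARE_SW",
    "ARE_CC",
    "ARE_CE",
    "FD_CC",
    "FD_CE",
    *(f"LEN_{d}" for d in _AXES4),
    *(f"MD_{d}" for d in _AXES4),
    *(f"MF_{d}" for d in _AXES4),
    *(f"MV_{d}" for d in _AXES4),
    "PD_P",
    "PD_V",
    "PP",
    *(f"RMSD_{d}" for d in _AXES4),
)

assert len(MEASURE_NAMES) == 43


@dataclass
class MeasureOptions:
    """Knobs of the measure pipeline (defaults match common practice)."""

    cutoff: float = 10.0
    filter_order: int = 4
    confidence: float = 0.95
    #: divide areas by trial duration ("per unit of time").
    time_normalized_areas: bool = True
    #: report LEN per second instead of per trial.
    len_per_second: bool = False
    #: AVG on axis directions as raw means instead of mean |detrended|.
    avg_raw: bool = False


@dataclass
class MeasureVector:
    """Named values of the 43 measures for one sensor x trial."""

    values: dict[str, float]
    #: names whose value is undefined on this input (kept as NaN).
    flags: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(MEASURE_NAMES))


def _series(d: DirectionalSignals) -> dict[str, np.ndarray]:
    return {"AP": d.ap, "ML": d.ml, "IS": d.is_, "2DR": d.r2d, "3DR": d.r3d}


def basic_stats(
    d: DirectionalSignals, avg_raw: bool = False
) -> dict[str, float]:
    """AVG, RNG, RMS for all five directions; MD, RMSD for the four
    trajectory directions.

    On already-centred axes MD coincides with AVG and RMSD with RMS;
    both names are kept because the measure registry lists them as
    separate families.
    """
    s = _series(d)
    if d.n < 2:
        raise ValueError("need at least 2 samples")
    out: dict[str, float] = {}
    for name, x in s.items():
        if name in ("2DR", "3DR"):
            out[f"AVG_{name}"] = float(np.mean(x))
        else:
            out[f"AVG_{name}"] = float(
                np.mean(x) if avg_raw else np.mean(np.abs(x))
            )
        out[f"RNG_{name}"] = float(np.max(x) - np.min(x))
        out[f"RMS_{name}"] = float(np.sqrt(np.mean(x**2)))
    for name in _AXES4:
        x = s[name]
        out[f"MD_{name}"] = float(np.mean(np.abs(x)))
        out[f"RMSD_{name}"] = float(np.sqrt(np.mean(x**2)))
    return out


def trajectory_length(
    d: DirectionalSignals, per_second: bool = False
) -> dict[str, float]:
    """Total path length of the trajectory in AP, ML, 2DR and 3DR."""
    if d.n < 2:
        raise ValueError("need at least 2 samples")
    dap, dml, dis = np.diff(d.ap), np.diff(d.ml), np.diff(d.is_)
    out = {
        "LEN_AP": float(np.sum(np.abs(dap))),
        "LEN_ML": float(np.sum(np.abs(dml))),
        "LEN_2DR": float(np.sum(np.hypot(dap, dml))),
        "LEN_3DR": float(np.sum(np.sqrt(dap**2 + dml**2 + dis**2))),
    }
    if per_second:
        out = {k: v / d.duration for k, v in out.items()}
    return out


def _resultant_sd(d: DirectionalSignals) -> tuple[float, float, float]:
    """(MD_2DR, RMSD_2DR, s_RD) of the planar resultant distances."""
    md = float(np.mean(d.r2d))
    rmsd = float(np.sqrt(np.mean(d.r2d**2)))
    s_rd = math.sqrt(max(rmsd**2 - md**2, 0.0))
    return md, rmsd, s_rd


def _ellipse_area(d: DirectionalSignals, confidence: float) -> float:
    """Area of the planar confidence ellipse (not time-normalised)."""
    n = d.n
    s_ap2 = float(np.mean(d.ap**2))
    s_ml2 = float(np.mean(d.ml**2))
    s_apml = float(np.mean(d.ap * d.ml))
    disc = max(s_ap2 * s_ml2 - s_apml**2, 0.0)
    fq = float(spst.f.ppf(confidence, 2, n - 2))
    return 2.0 * math.pi * fq * math.sqrt(disc)


def area_measures(
    d: DirectionalSignals,
    confidence: float = 0.95,
    time_normalized: bool = True,
) -> tuple[dict[str, float], set[str]]:
    """Sway area (triangle sweep), 95% confidence circle and ellipse.

    ARE_SW sums the triangles swept about the trajectory centre,
    ARE_CC = pi (MD + z * s_RD)^2 with z = 1.645, and
    ARE_CE = 2 pi F_{1-conf}[2, n-2] sqrt(s_AP^2 s_ML^2 - s_APML^2).
    All three are divided by trial duration when ``time_normalized``.
    """
    if d.n < 3:
        raise ValueError("need at least 3 samples")
    flags: set[str] = set()
    t = d.duration if time_normalized else 1.0
    sweep = 0.5 * np.sum(np.abs(d.ap[:-1] * d.ml[1:] - d.ap[1:] * d.ml[:-1]))
    md, _, s_rd = _resultant_sd(d)
    # one-sided bound on the resultant distance: z = 1.645 at 95%
    z = float(spst.norm.ppf(confidence))
    cc = math.pi * (md + z * s_rd) ** 2
    ce = _ellipse_area(d, confidence)
    out = {"ARE_SW": float(sweep) / t, "ARE_CC": cc / t, "ARE_CE": ce / t}
    if md == 0.0 and s_rd == 0.0:
        flags.update(out)
    return out, flags


def fractal_dimension(
    d: DirectionalSignals, confidence: float = 0.95
) -> tuple[dict[str, float], set[str]]:
    """Fractal dimension of the planar trajectory, FD = ln N / ln(N d / L).

    The characteristic diameter d is taken from the 95% confidence
    circle (FD_CC) or from the circle whose area equals the 95%
    confidence ellipse (FD_CE). Scale-invariant; undefined (NaN,
    flagged) for degenerate trajectories.
    """
    n = d.n
    if n < 3:
        raise ValueError("need at least 3 samples")
    flags: set[str] = set()
    length = trajectory_length(d)["LEN_2DR"]
    md, _, s_rd = _resultant_sd(d)
    z = float(spst.norm.ppf(confidence))
    d_cc = 2.0 * (md + z * s_rd)
    d_ce = math.sqrt(8.0 * _ellipse_area(d, confidence) / math.pi)
    out: dict[str, float] = {}
    for name, diam in (("FD_CC", d_cc), ("FD_CE", d_ce)):
        if length <= 0 or diam <= 0:
            out[name] = float("nan")
            flags.add(name)
            continue
        denom = math.log(n * diam / length)
        if denom <= 0:
            out[name] = float("nan")
            flags.add(name)
        else:
            out[name] = math.log(n) / denom
    return out, flags


def mean_frequency(
    d: DirectionalSignals,
) -> tuple[dict[str, float], set[str]]:
    """Power-weighted mean frequency of the one-sided spectrum, DC
    excluded; resultant directions use the centred resultant series."""
    if d.n < 16:
        raise ValueError("need at least 16 samples")
    flags: set[str] = set()
    out: dict[str, float] = {}
    for name in _AXES4:
        x = _series(d)[name]
        x = x - x.mean()
        freqs, power = sps.periodogram(x, fs=d.rate, detrend=False)
        freqs, power = freqs[1:], power[1:]
        total = power.sum()
        if total <= 0:
            out[f"MF_{name}"] = float("nan")
            flags.add(f"MF_{name}")
        else:
            out[f"MF_{name}"] = float((freqs * power).sum() / total)
    return out, flags


def _integrate_detrend(x: np.ndarray, rate: float) -> np.ndarray:
    """Cumulative trapezoidal integral, linearly detrended to kill drift."""
    v = spi.cumulative_trapezoid(x, dx=1.0 / rate, initial=0.0)
    return sps.detrend(v, type="linear")


def integrate_measures(d: DirectionalSignals) -> dict[str, float]:
    """Velocity/displacement statistics: MV, PD_P, PD_V and PP.

    The acceleration is integrated once (velocity) and twice
    (displacement) with linear detrending after each pass. MV is the
    mean magnitude of the velocity (resultants combine axis
    velocities); PD_P/PD_V are planar deviations sqrt(var_AP + var_ML)
    of displacement/velocity; PP is the sagittal (AP) phase-plane
    parameter sqrt(var(p_AP) + var(v_AP)).
    """
    rate = d.rate
    v = {a: _integrate_detrend(_series(d)[a], rate) for a in ("AP", "ML", "IS")}
    p = {a: _integrate_detrend(v[a], rate) for a in ("AP", "ML")}
    out = {
        "MV_AP": float(np.mean(np.abs(v["AP"]))),
        "MV_ML": float(np.mean(np.abs(v["ML"]))),
        "MV_2DR": float(np.mean(np.hypot(v["AP"], v["ML"]))),
        "MV_3DR": float(
            np.mean(np.sqrt(v["AP"] ** 2 + v["ML"] ** 2 + v["IS"] ** 2))
        ),
        "PD_P": float(np.sqrt(np.var(p["AP"]) + np.var(p["ML"]))),
        "PD_V": float(np.sqrt(np.var(v["AP"]) + np.var(v["ML"]))),
        "PP": float(np.sqrt(np.var(p["AP"]) + np.var(v["AP"]))),
    }
    return out


def rotational_mean_frequency(d: DirectionalSignals) -> dict[str, float]:
    """Rotational MFREQ = MV / (2 pi MD) per axis — the classical
    stabilometry alternative to the spectral MF; not part of the 43."""
    mv = integrate_measures(d)
    md = basic_stats(d)
    out = {}
    for a in ("AP", "ML"):
        denom = 2 * math.pi * md[f"MD_{a}"]
        out[f"MFREQ_ROT_{a}"] = mv[f"MV_{a}"] / denom if denom > 0 else float("nan")
    return out


def compute_measures(
    d: DirectionalSignals, opts: MeasureOptions | None = None
) -> MeasureVector:
    """All 43 measures from one preprocessed directional-signal set."""
    opts = opts or MeasureOptions()
    values: dict[str, float] = {}
    flags: set[str] = set()
    values.update(basic_stats(d, avg_raw=opts.avg_raw))
    values.update(trajectory_length(d, per_second=opts.len_per_second))
    areas, f = area_measures(
        d, confidence=opts.confidence, time_normalized=opts.time_normalized_areas
    )
    values.update(areas)
    flags |= f
    fd, f = fractal_dimension(d, confidence=opts.confidence)
    values.update(fd)
    flags |= f
    mf, f = mean_frequency(d)
    values.update(mf)
    flags |= f
    values.update(integrate_measures(d))
    ordered = {name: values[name] for name in MEASURE_NAMES}
    return MeasureVector(values=ordered, flags=flags)


def compute_all_measures(
    recording: TrialRecording,
    sensor: str,
    opts: MeasureOptions | None = None,
) -> MeasureVector:
    """Preprocess one sensor of a trial and compute the 43 measures."""
    opts = opts or MeasureOptions()
    if sensor not in recording.acc:
        raise KeyError(f"sensor {sensor!r} not in recording")
    d = preprocess_acc(
        recording.acc[sensor],
        recording.acc_rate,
        cutoff=opts.cutoff,
        order=opts.filter_order,
    )
    return compute_measures(d, opts)


def copv_ap(cop: np.ndarray, rate: float) -> float:
    """Mean AP velocity of the COP: total AP path length / duration (mm/s).

    Expects an already-filtered trajectory; apply
    :func:`swaylab.preprocessing.preprocess_cop` first for raw data.
    """
    cop = np.asarray(cop, dtype=float)
    ap = cop[:, 0] if cop.ndim == 2 else cop
    if ap.size < 2:
        raise ValueError("need at least 2 samples")
    duration = ap.size / rate
    return float(np.sum(np.abs(np.diff(ap))) / duration)


def trial_copv_ap(
    recording: TrialRecording, cutoff: float = 10.0, order: int = 4
) -> float:
    """COPV_AP of one trial, filtering the raw COP trajectory first."""
    filtered = preprocess_cop(
        recording.cop, recording.cop_rate, cutoff=cutoff, order=order
    )
    return copv_ap(filtered, recording.cop_rate)


def compute_study_measures(
    dataset: StudyDataset,
    sensors: list[str] | None = None,
    opts: MeasureOptions | None = None,
    include_copv: bool = True,
) -> pd.DataFrame:
    """Wide measure table for a study: one row per trial x sensor.

    Columns: subject, posture, surface, load, repetition, sensor, pps,
    copv_ap (study-level, repeated across sensors) and the 43 measures.
    """
    opts = opts or MeasureOptions()
    sensors = list(sensors or dataset.config.sensor_set)
    rows = []
    for trial in dataset.trials:
        copv = (
            trial_copv_ap(trial, cutoff=opts.cutoff, order=opts.filter_order)
            if include_copv
            else float("nan")
        )
        for sensor in sensors:
            vec = compute_all_measures(trial, sensor, opts)
            row = {
                "subject": trial.subject_id,
                "posture": trial.condition.posture,
                "surface": trial.condition.surface,
                "load": trial.condition.load,
                "repetition": trial.repetition,
                "sensor": sensor,
                "pps": trial.pps,
                "copv_ap": copv,
            }
            row.update(vec.values)
            rows.append(row)
    return pd.DataFrame(rows)


def measures_to_tidy(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide measure table into tidy (.., measure, value) form."""
    meta = ["subject", "posture", "surface", "load", "repetition", "sensor"]
    return wide.melt(
        id_vars=[c for c in meta if c in wide.columns],
        value_vars=[m for m in MEASURE_NAMES if m in wide.columns],
        var_name="measure",
        value_name="value",
    )
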