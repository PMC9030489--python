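"""Independent brute-force transcriptions of the sway-measure definitions.

Deliberately written with explicit loops and its own spectral /
integration code so it shares no computational path with the package
implementation; used only as a reference in tests.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as spst


def _linear_detrend(x: list[float]) -> list[float]:
    n = len(x)
    t = np.arange(n, dtype=float)
    a = np.vstack([t, np.ones(n)]).T
    coef, *_ = np.linalg.lstsq(a, np.asarray(x, dtype=float), rcond=None)
    return [x[i] - (coef[0] * i + coef[1]) for i in range(n)]


def _cumtrapz(x: list[float], dt: float) -> list[float]:
    out = [0.0]
    for i in range(1, len(x)):
        out.append(out[-1] + 0.5 * (x[i - 1] + x[i]) * dt)
    return out


def _periodogram_onesided(x: list[float], rate: float):
    """One-sided periodogram with the conventional density scaling."""
    n = len(x)
    spec = np.fft.rfft(np.asarray(x, dtype=float))
    p = (np.abs(spec) ** 2) / (rate * n)
    if n % 2 == 0:
        p[1:-1] *= 2.0
    else:
        p[1:] *= 2.0
    freqs = [k * rate / n for k in range(len(p))]
    return freqs, list(p)


def oracle_measures(acc: np.ndarray, rate: float) -> dict[str, float]:
    """All 43 measures of one (n, 3) AP/ML/IS block, by direct formula."""
    n = acc.shape[0]
    t_dur = n / rate
    means = [sum(acc[:, j]) / n for j in range(3)]
    ap = [acc[i, 0] - means[0] for i in range(n)]
    ml = [acc[i, 1] - means[1] for i in range(n)]
    is_ = [acc[i, 2] - means[2] for i in range(n)]
    r2d = [math.hypot(ap[i], ml[i]) for i in range(n)]
    r3d = [math.sqrt(ap[i] ** 2 + ml[i] ** 2 + is_[i] ** 2) for i in range(n)]
    series = {"AP": ap, "ML": ml, "IS": is_, "2DR": r2d, "3DR": r3d}

    out: dict[str, float] = {}
    for name, x in series.items():
        if name in ("2DR", "3DR"):
            out[f"AVG_{name}"] = sum(x) / n
        else:
            out[f"AVG_{name}"] = sum(abs(v) for v in x) / n
        out[f"RNG_{name}"] = max(x) - min(x)
        out[f"RMS_{name}"] = math.sqrt(sum(v * v for v in x) / n)
    for name in ("AP", "ML", "2DR", "3DR"):
        x = series[name]
        out[f"MD_{name}"] = sum(abs(v) for v in x) / n
        out[f"RMSD_{name}"] = math.sqrt(sum(v * v for v in x) / n)

    len_ap = sum(abs(ap[i + 1] - ap[i]) for i in range(n - 1))
    len_ml = sum(abs(ml[i + 1] - ml[i]) for i in range(n - 1))
    len_2d = sum(
        math.hypot(ap[i + 1] - ap[i], ml[i + 1] - ml[i]) for i in range(n - 1)
    )
    len_3d = sum(
        math.sqrt(
            (ap[i + 1] - ap[i]) ** 2
            + (ml[i + 1] - ml[i]) ** 2
            + (is_[i + 1] - is_[i]) ** 2
        )
        for i in range(n - 1)
    )
    out.update(LEN_AP=len_ap, LEN_ML=len_ml, LEN_2DR=len_2d, LEN_3DR=len_3d)

    sweep = sum(
        0.5 * abs(ap[i] * ml[i + 1] - ap[i + 1] * ml[i]) for i in range(n - 1)
    )
    md = out["MD_2DR"]
    rmsd = out["RMSD_2DR"]
    s_rd = math.sqrt(max(rmsd**2 - md**2, 0.0))
    z = spst.norm.ppf(0.95)
    s_ap2 = sum(v * v for v in ap) / n
    s_ml2 = sum(v * v for v in ml) / n
    s_apml = sum(ap[i] * ml[i] for i in range(n)) / n
    fq = spst.f.ppf(0.95, 2, n - 2)
    area_ce = 2.0 * math.pi * fq * math.sqrt(
        max(s_ap2 * s_ml2 - s_apml**2, 0.0)
    )
    out["ARE_SW"] = sweep / t_dur
    out["ARE_CC"] = math.pi * (md + z * s_rd) ** 2 / t_dur
    out["ARE_CE"] = area_ce / t_dur

    d_cc = 2.0 * (md + z * s_rd)
    d_ce = math.sqrt(8.0 * area_ce / math.pi)
    for name, diam in (("FD_CC", d_cc), ("FD_CE", d_ce)):
        out[name] = math.log(n) / math.log(n * diam / len_2d)

    for name in ("AP", "ML", "2DR", "3DR"):
        x = series[name]
        mean_x = sum(x) / n
        centred = [v - mean_x for v in x]
        freqs, power = _periodogram_onesided(centred, rate)
        num = sum(freqs[k] * power[k] for k in range(1, len(power)))
        den = sum(power[k] for k in range(1, len(power)))
        out[f"MF_{name}"] = num / den

    dt = 1.0 / rate
    v = {a: _linear_detrend(_cumtrapz(series[a], dt)) for a in ("AP", "ML", "IS")}
    p = {a: _linear_detrend(_cumtrapz(v[a], dt)) for a in ("AP", "ML")}
    out["MV_AP"] = sum(abs(x) for x in v["AP"]) / n
    out["MV_ML"] = sum(abs(x) for x in v["ML"]) / n
    out["MV_2DR"] = sum(
        math.hypot(v["AP"][i], v["ML"][i]) for i in range(n)
    ) / n
    out["MV_3DR"] = sum(
        math.sqrt(v["AP"][i] ** 2 + v["ML"][i] ** 2 + v["IS"][i] ** 2)
        for i in range(n)
    ) / n

    def _var(x: list[float]) -> float:
        m = sum(x) / len(x)
        return sum((u - m) ** 2 for u in x) / len(x)

    out["PD_P"] = math.sqrt(_var(p["AP"]) + _var(p["ML"]))
    out["PD_V"] = math.sqrt(_var(v["AP"]) + _var(v["ML"]))
    out["PP"] = math.sqrt(_var(p["AP"]) + _var(v["AP"]))
    return out
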