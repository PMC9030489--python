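"""Factor-effect detection: three-way repeated-measures ANOVA with
sphericity handling, paired t-tests, normality diagnostics and
detection-count summaries.

The design is fully within-subject: every subject contributes a mean
value (repetitions averaged) in each of the 24 cells of the
WP (posture, 6) x SS (surface, 2) x LC (load, 2) factorial. Each
effect is tested against its own effect-by-subject interaction. For
effects involving the six-level posture factor, Mauchly's sphericity
test is computed on the orthonormal contrast scores and, when it
rejects at alpha, the Greenhouse-Geisser epsilon multiplies both
degrees of freedom. Two-level effects have a single contrast, so
sphericity holds trivially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spst
from scipy.linalg import helmert

from .design import LOADS, POSTURES, SURFACES

__all__ = [
    "RMAnova",
    "RMAnovaResults",
    "EFFECTS",
    "rm_anova_cells",
    "mauchly_test",
    "gg_epsilon",
    "paired_ttests",
    "shapiro_by_cell",
    "detection_summary",
]

_FACTOR_LEVELS = (len(POSTURES), len(SURFACES), len(LOADS))  # (6, 2, 2)
_FACTOR_LABELS = ("WP", "SS", "LC")

#: effect label -> tuple of involved factor indices (0=WP, 1=SS, 2=LC),
#: in the conventional reporting order.
EFFECTS: dict[str, tuple[int, ...]] = {
    "SS": (1,),
    "LC": (2,),
    "WP": (0,),
    "SSxLC": (1, 2),
    "SSxWP": (0, 1),
    "LCxWP": (0, 2),
    "SSxLCxWP": (0, 1, 2),
}

MAIN_EFFECTS = ("SS", "LC", "WP")
INTERACTION_EFFECTS = ("SSxLC", "SSxWP", "LCxWP", "SSxLCxWP")


class BalancedDesignError(ValueError):
    """The within-subject design is incomplete or too small."""


def _effect_contrasts(involved: tuple[int, ...]) -> np.ndarray:
    """Orthogonal contrast matrix (d x 24) for one effect.

    Kronecker product over the three factors: orthonormal Helmert
    contrasts for involved factors, the plain level average for the
    others. Rows have equal norm, as required for Mauchly/epsilon.
    """
    mat = np.ones((1, 1))
    for idx, k in enumerate(_FACTOR_LEVELS):
        part = helmert(k) if idx in involved else np.full((1, k), 1.0 / k)
        mat = np.kron(mat, part)
    return mat


def contrast_scores(cells: np.ndarray, effect: str) -> np.ndarray:
    """Per-subject contrast scores (n x d) for one effect.

    ``cells`` is the (n_subjects x 24) matrix of cell means in
    posture-major, then surface, then load order.
    """
    return cells @ _effect_contrasts(EFFECTS[effect]).T


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast scores (n x d ≥ 2),
    clamped to [1/d, 1]."""
    d = scores.shape[1]
    if d < 2:
        return 1.0
    sigma = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(sigma)
    tr2 = np.trace(sigma @ sigma)
    if tr2 <= 0:
        return 1.0 / d
    eps = tr**2 / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_test(scores: np.ndarray) -> dict[str, float]:
    """Mauchly's sphericity test on contrast scores (n x d).

    Returns W, chi2, df and p. For d = 1 (two-level effects) the test
    is not applicable and W = 1, p = 1 by convention.
    """
    n, d = scores.shape
    if d < 2:
        return {"W": 1.0, "chi2": 0.0, "df": 0.0, "p": 1.0}
    if n - 1 <= d:
        # covariance is singular: test undefined
        return {"W": float("nan"), "chi2": float("nan"), "df": float("nan"), "p": float("nan")}
    sigma = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(sigma)
    det = np.linalg.det(sigma)
    if tr <= 0 or det <= 0:
        return {"W": 0.0, "chi2": float("inf"), "df": d * (d + 1) / 2 - 1, "p": 0.0}
    w = det / (tr / d) ** d
    fcorr = (n - 1) - (2 * d**2 + d + 2) / (6.0 * d)
    chi2 = -fcorr * np.log(w)
    df = d * (d + 1) / 2 - 1
    p = float(spst.chi2.sf(chi2, df))
    return {"W": float(w), "chi2": float(chi2), "df": float(df), "p": p}


def rm_anova_cells(cells: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Three-way within-subject ANOVA from an (n_subjects x 24) cell
    matrix; one row per effect.

    Columns: F, df1, df2, eps, p_uncorrected, p, mauchly_W, mauchly_p,
    gg_applied, significant. The Greenhouse-Geisser correction is
    applied (both df multiplied by epsilon) whenever the effect has
    more than one contrast and Mauchly's test rejects at ``alpha``.
    """
    cells = np.asarray(cells, dtype=float)
    n = cells.shape[0]
    if cells.ndim != 2 or cells.shape[1] != 24:
        raise BalancedDesignError(f"expected (n, 24) cell means, got {cells.shape}")
    if n < 2:
        raise BalancedDesignError("need at least 2 subjects")
    if np.isnan(cells).any():
        raise BalancedDesignError("cell means contain missing values")
    rows = []
    for effect in EFFECTS:
        z = contrast_scores(cells, effect)
        d = z.shape[1]
        zbar = z.mean(axis=0)
        ss_eff = n * float(zbar @ zbar)
        resid = z - zbar
        ss_err = float((resid**2).sum())
        df1, df2 = d, d * (n - 1)
        if ss_err <= 0:
            f_stat = float("inf") if ss_eff > 0 else 0.0
        else:
            f_stat = (ss_eff / df1) / (ss_err / df2)
        p_unc = float(spst.f.sf(f_stat, df1, df2))
        mauchly = mauchly_test(z)
        eps = gg_epsilon(z)
        gg_applied = bool(
            d > 1 and np.isfinite(mauchly["p"]) and mauchly["p"] < alpha
        )
        if gg_applied:
            p = float(spst.f.sf(f_stat, df1 * eps, df2 * eps))
            rdf1, rdf2 = df1 * eps, df2 * eps
        else:
            p, rdf1, rdf2 = p_unc, float(df1), float(df2)
        rows.append(
            {
                "effect": effect,
                "F": f_stat,
                "df1": rdf1,
                "df2": rdf2,
                "eps": eps if d > 1 else 1.0,
                "p_uncorrected": p_unc,
                "p": p,
                "mauchly_W": mauchly["W"],
                "mauchly_p": mauchly["p"],
                "gg_applied": gg_applied,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def subject_cell_means(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    factors: tuple[str, str, str] = ("posture", "surface", "load"),
) -> np.ndarray:
    """Average repetitions and pivot to the (n_subjects x 24) matrix.

    Raises :class:`BalancedDesignError` if any subject is missing any
    of the 24 cells.
    """
    f_post, f_surf, f_load = factors
    grouped = (
        data.groupby([subject, f_post, f_surf, f_load], observed=True)[dv]
        .mean()
        .reset_index()
    )
    pivot = grouped.pivot_table(
        index=subject, columns=[f_post, f_surf, f_load], values=dv
    )
    full_cols = pd.MultiIndex.from_product([POSTURES, SURFACES, LOADS])
    missing = full_cols.difference(pivot.columns)
    if len(missing):
        raise BalancedDesignError(f"missing design cells: {list(missing)[:5]}")
    pivot = pivot.reindex(columns=full_cols)
    if pivot.isna().any().any():
        bad = pivot.index[pivot.isna().any(axis=1)].tolist()
        raise BalancedDesignError(f"incomplete subjects: {bad[:5]}")
    return pivot.to_numpy()


class RMAnova:
    """Three-way repeated-measures ANOVA model for one sway measure.

    Parameters
    ----------
    data:
        Long-format table with one row per trial (or per averaged
        condition) containing the subject, factor and response columns.
    dv:
        Name of the response column.
    subject, factors:
        Column names identifying the subject and the (posture,
        surface, load) factors.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        subject: str = "subject",
        factors: tuple[str, str, str] = ("posture", "surface", "load"),
    ) -> None:
        self.data = data
        self.dv = dv
        self.subject = subject
        self.factors = factors
        self.cells = subject_cell_means(data, dv, subject, factors)

    def fit(self, alpha: float = 0.05) -> "RMAnovaResults":
        table = rm_anova_cells(self.cells, alpha=alpha)
        return RMAnovaResults(self, table, alpha)


@dataclass
class RMAnovaResults:
    """Fitted effect table plus convenience accessors."""

    model: RMAnova
    anova_table: pd.DataFrame
    alpha: float

    @property
    def pvalues(self) -> pd.Series:
        return self.anova_table["p"]

    def significant_effects(self) -> list[str]:
        return list(self.anova_table.index[self.anova_table["significant"]])

    def summary(self) -> str:
        n = self.model.cells.shape[0]
        lines = [
            f"Three-way repeated-measures ANOVA on '{self.model.dv}' "
            f"(n={n} subjects, alpha={self.alpha})",
            f"{'effect':<10}{'F':>10}{'df1':>8}{'df2':>9}{'eps':>7}"
            f"{'p':>10}  {'GG':>3}  sig",
        ]
        for eff, row in self.anova_table.iterrows():
            lines.append(
                f"{eff:<10}{row.F:>10.3f}{row.df1:>8.2f}{row.df2:>9.2f}"
                f"{row.eps:>7.3f}{row.p:>10.4f}  {'yes' if row.gg_applied else ' no'}"
                f"  {'*' if row.significant else ''}"
            )
        return "\n".join(lines)


def paired_ttests(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "subject",
    correction: str = "none",
) -> pd.DataFrame:
    """All pairwise paired t-tests on subject-level marginal means.

    ``correction`` is ``"none"`` (raw p, as the detection counts use)
    or ``"holm"``. Zero-variance difference pairs are reported with
    t = 0, p = 1 and flagged.
    """
    marginals = (
        data.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    )
    levels = list(marginals.columns)
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            diff = marginals[a] - marginals[b]
            if np.allclose(diff, diff.iloc[0]) and np.allclose(diff.std(ddof=1), 0):
                if np.allclose(diff, 0):
                    t, p, flag = 0.0, 1.0, True
                else:
                    t, p, flag = float("inf"), 0.0, True
            else:
                t, p = spst.ttest_rel(marginals[a], marginals[b])
                flag = False
            rows.append(
                {"level_a": a, "level_b": b, "t": float(t), "p": float(p),
                 "df": len(marginals) - 1, "degenerate": flag}
            )
    out = pd.DataFrame(rows)
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        out["p_corrected"] = multipletests(out["p"], method="holm")[1]
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return out


def shapiro_by_cell(
    data: pd.DataFrame,
    dv: str,
    factors: tuple[str, str, str] = ("posture", "surface", "load"),
) -> pd.DataFrame:
    """Shapiro-Wilk normality diagnostics per design cell.

    Reported for inspection only; the ANOVA path never branches on it.
    """
    rows = []
    for keys, grp in data.groupby(list(factors), observed=True):
        vals = grp[dv].to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            w, p = spst.shapiro(vals)
        else:
            w, p = float("nan"), float("nan")
        rows.append(dict(zip(factors, keys)) | {"W": w, "p": p, "n": len(vals)})
    return pd.DataFrame(rows)


def detection_summary(
    effect_tables: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Detection counts per sensor: how many measures reach p < alpha.

    ``effect_tables`` maps (sensor, measure) to an effect table as
    returned by :func:`rm_anova_cells`. The output has one row per
    sensor, one column per effect, plus main-effect and
    interaction-effect sums.
    """
    sensors = sorted({s for s, _ in effect_tables})
    rows = []
    for sensor in sensors:
        counts = {eff: 0 for eff in EFFECTS}
        for (s, _), table in effect_tables.items():
            if s != sensor:
                continue
            for eff in EFFECTS:
                if table.loc[eff, "p"] < alpha:
                    counts[eff] += 1
        row: dict[str, object] = {"sensor": sensor}
        row.update({eff: counts[eff] for eff in ("SS", "LC", "WP")})
        row["main_sum"] = sum(counts[e] for e in MAIN_EFFECTS)
        row.update({eff: counts[eff] for eff in INTERACTION_EFFECTS})
        row["interaction_sum"] = sum(counts[e] for e in INTERACTION_EFFECTS)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sensor")


def run_effects_battery(
    measures_wide: pd.DataFrame,
    measure_names: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA battery over every sensor x measure in a wide measure table.

    Returns (long results table, detection summary). The long table has
    one row per sensor x measure x effect.
    """
    from .measures import MEASURE_NAMES

    measure_names = list(measure_names or MEASURE_NAMES)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    long_rows = []
    for sensor, sub in measures_wide.groupby("sensor", observed=True):
        # one pivot pass for all measures of this sensor
        grouped = (
            sub.groupby(["subject", "posture", "surface", "load"], observed=True)[
                measure_names
            ]
            .mean()
            .reset_index()
        )
        for measure in measure_names:
            cells = subject_cell_means(grouped, measure)
            table = rm_anova_cells(cells, alpha=alpha)
            tables[(sensor, measure)] = table
            for eff, row in table.iterrows():
                long_rows.append(
                    {
                        "sensor": sensor,
                        "measure": measure,
                        "effect": eff,
                        "F": row.F,
                        "df1": row.df1,
                        "df2": row.df2,
                        "eps": row.eps,
                        "p": row.p,
                        "significant": row.significant,
                    }
                )
    summary = detection_summary(tables, alpha=alpha)
    return pd.DataFrame(long_rows), summary
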