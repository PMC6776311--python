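"""Stable-isotope niche and trophic statistics for per-scat delta values.

Delta notation expresses an isotope ratio relative to a standard:

    delta = (R_sample / R_standard - 1) * 1000   [permil]

with R = heavy / light isotope (AIR standard for N, VPDB for C). The
variance of a consumer population's delta values is treated as an isotopic
niche-width metric: group variances are compared with Levene's
homoscedasticity test (center configurable, classical mean-centered by
default). Mean delta-15N is compared across rivers and years with a
two-factor ANOVA (sequential Type-I sums of squares, with interaction) on
log-transformed values, followed by pairwise two-sample t-tests with
Bonferroni-adjusted p-values. Shapiro-Wilk normality checks are advisory
only and never block the pipeline.

Hypothesis-test machinery is delegated to scipy/statsmodels; this module
owns the study design around it (grouping, contrasts, policies, errors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "LeveneResult",
    "GroupVarianceSummary",
    "NormalityResult",
    "AnovaResult",
    "delta_value",
    "variance_niche",
    "normality_check",
    "anova_two_factor",
    "pairwise_t_bonferroni",
]


def delta_value(r_sample: float, r_standard: float) -> float:
    """Per-mil delta value of an isotope ratio against its standard."""
    if r_standard <= 0:
        raise ValueError("r_standard must be positive")
    if r_sample < 0:
        raise ValueError("r_sample must be non-negative")
    return (r_sample / r_standard - 1.0) * 1000.0


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    pvalue: float
    center: str
    groups: tuple[str, ...]


@dataclass
class GroupVarianceSummary:
    """Per-group dispersion of one isotope plus Levene comparisons."""

    isotope: str
    per_group: pd.DataFrame  # river, year, n, mean, variance
    omnibus: LeveneResult
    pairwise: list[LeveneResult] = field(default_factory=list)
    center: str = "mean"


def _group_label(river: str, year: int) -> str:
    return f"{river} {year}"


def variance_niche(
    samples: pd.DataFrame,
    isotope: str = "d15N",
    center: str = "mean",
    contrasts: Sequence[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> GroupVarianceSummary:
    """Group variances of delta values with omnibus and pairwise Levene tests.

    ``samples`` is a frame with river, year and the isotope column.
    Contaminated scats must be excluded upstream. Each group needs n >= 2
    (a variance is undefined otherwise); default contrasts are all pairs.
    """
    if center not in {"mean", "median"}:
        raise ValueError("center must be 'mean' or 'median'")
    if isotope not in samples.columns:
        raise ValueError(f"no column {isotope!r} in samples")
    keys = sorted({(r, int(y)) for r, y in zip(samples["river"], samples["year"])})
    if len(keys) < 2:
        raise ValueError("need >= 2 groups to compare variances")
    values: dict[tuple[str, int], np.ndarray] = {}
    rows = []
    for river, year in keys:
        v = samples.loc[
            (samples["river"] == river) & (samples["year"] == year), isotope
        ].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(
                f"group {_group_label(river, year)!r} has n={v.size} < 2; "
                "variance undefined"
            )
        values[(river, year)] = v
        rows.append((river, year, v.size, float(v.mean()), float(v.var(ddof=1))))
    per_group = pd.DataFrame(rows, columns=["river", "year", "n", "mean", "variance"])
    w, p = stats.levene(*values.values(), center=center)
    omnibus = LeveneResult(
        float(w), float(p), center, tuple(_group_label(r, y) for r, y in keys)
    )
    if contrasts is None:
        contrasts = [(keys[i], keys[j]) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    pairwise = []
    for a, b in contrasts:
        for g in (a, b):
            if tuple(g) not in values:
                raise ValueError(f"contrast names unknown group {g!r}")
        w, p = stats.levene(values[tuple(a)], values[tuple(b)], center=center)
        pairwise.append(
            LeveneResult(
                float(w), float(p), center, (_group_label(*a), _group_label(*b))
            )
        )
    return GroupVarianceSummary(
        isotope=isotope, per_group=per_group, omnibus=omnibus, pairwise=pairwise, center=center
    )


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    pvalue: float
    verdict: str  # "normal" | "non-normal" | "degenerate" | "not assessed"


def normality_check(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk check, advisory only (3 <= n <= 5000)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 3 or v.size > 5000:
        warnings.warn(
            f"Shapiro-Wilk not assessed for n={v.size} (valid range 3..5000)",
            stacklevel=2,
        )
        return NormalityResult(np.nan, np.nan, "not assessed")
    if np.ptp(v) == 0:
        warnings.warn("constant sample; normality check degenerate", stacklevel=2)
        return NormalityResult(np.nan, np.nan, "degenerate")
    w, p = stats.shapiro(v)
    return NormalityResult(float(w), float(p), "normal" if p > alpha else "non-normal")


@dataclass
class AnovaResult:
    """Type-I two-factor ANOVA table plus the transform applied."""

    table: pd.DataFrame  # index: river, year, interaction, residual
    log_transformed: bool

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def anova_two_factor(
    values: Sequence[float],
    factor_river: Sequence[str],
    factor_year: Sequence[int],
    log_transform: bool = True,
) -> AnovaResult:
    """Two-factor ANOVA with interaction, sequential (Type-I) sums of squares.

    ``log_transform`` applies the natural log (requires strictly positive
    values; appropriate for delta-15N in this system, never for delta-13C).
    Empty design cells and zero residual variance are errors.
    """
    y = np.asarray(list(values), dtype=float)
    river = pd.Series(list(factor_river), dtype=str, name="river")
    year = pd.Series([int(v) for v in factor_year], name="year")
    if not (len(y) == len(river) == len(year)):
        raise ValueError("values and factors must have equal length")
    if river.nunique() < 2 or year.nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells = pd.crosstab(river, year)
    empty = [(r, c) for r in cells.index for c in cells.columns if cells.loc[r, c] == 0]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")
    if log_transform:
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        y = np.log(y)
    df = pd.DataFrame({"y": y, "river": river, "year": year.astype(str)})
    model = smf.ols("y ~ C(river) * C(year)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    if table.loc["Residual", "sum_sq"] <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        raise ValueError("zero residual variance; F statistics undefined")
    table = table.rename(
        index={
            "C(river)": "river",
            "C(year)": "year",
            "C(river):C(year)": "interaction",
            "Residual": "residual",
        }
    )
    return AnovaResult(table=table, log_transformed=log_transform)


def pairwise_t_bonferroni(
    values: Sequence[float],
    groups: Sequence[str],
    contrasts: Sequence[tuple[str, str]],
    equal_var_policy: str = "auto",
) -> pd.DataFrame:
    """Pairwise two-sample t-tests with Bonferroni-adjusted p-values.

    ``equal_var_policy``: "pooled" (classical), "welch", or "auto" —
    Welch when a pairwise Levene test rejects equal variances at 0.05,
    pooled otherwise. Adjusted p = min(1, raw p * number of contrasts).
    Columns: group_a, group_b, t, df, p_raw, p_adj, test.
    """
    if equal_var_policy not in {"auto", "pooled", "welch"}:
        raise ValueError("equal_var_policy must be 'auto', 'pooled' or 'welch'")
    y = np.asarray(list(values), dtype=float)
    g = np.asarray(list(groups), dtype=object)
    if y.size != g.size:
        raise ValueError("values and groups must have equal length")
    by_group = {name: y[g == name] for name in pd.unique(g)}
    m = len(contrasts)
    rows = []
    for a, b in contrasts:
        for name in (a, b):
            if name not in by_group:
                raise ValueError(f"contrast names unknown group {name!r}")
        va, vb = by_group[a], by_group[b]
        if va.size < 2 or vb.size < 2:
            raise ValueError(f"contrast ({a!r}, {b!r}): both groups need n >= 2")
        if equal_var_policy == "auto":
            _, lev_p = stats.levene(va, vb, center="mean")
            pooled = lev_p >= 0.05
        else:
            pooled = equal_var_policy == "pooled"
        res = stats.ttest_ind(va, vb, equal_var=pooled)
        rows.append(
            (
                a,
                b,
                float(res.statistic),
                float(res.df),
                float(res.pvalue),
                float(min(1.0, res.pvalue * m)),
                "pooled" if pooled else "welch",
            )
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "t", "df", "p_raw", "p_adj", "test"]
    )
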