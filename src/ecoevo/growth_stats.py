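"""Growth-rate (Malthusian fitness) computation and the ANOVA suite over it.

Growth of a population over one serial-transfer cycle is summarised by the
Malthusian parameter m = ln(N_final / N_initial), the standard fitness proxy
in experimental evolution. Rates measured alone versus alongside a resident
community are compared with a two-way fixed-effects ANOVA (treatment x
growth-condition, with interaction); final relative abundances in
competition are compared with a one-way ANOVA plus Tukey HSD pairwise
contrasts; mutation counts (heteroscedastic small groups) use Welch's ANOVA.

The default Malthusian unit is the whole growth cycle (ln-fold change over
the assay, 6 days in the source design); ``per_day=True`` divides by the
duration. The choice rescales rates by a common constant and leaves every F
statistic unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DesignError, SchemaError

__all__ = [
    "GROWTH_COLUMNS",
    "WelchAnovaResult",
    "malthusian",
    "malthusian_table",
    "growth_interaction_anova",
    "competition_oneway_anova",
    "welch_anova",
]

GROWTH_COLUMNS = ["population_id", "treatment", "condition", "t0_cfu", "t6_cfu"]


@dataclass(frozen=True)
class WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA: F, numerator/denominator df, p."""

    F: float
    df1: float
    df2: float
    p: float

    def as_dict(self) -> dict:
        return {"F": self.F, "df1": self.df1, "df2": self.df2, "p": self.p}


def malthusian(n0: float, nf: float, duration: float = 6.0, per_day: bool = False) -> float:
    """Malthusian parameter ln(nf / n0); per day if ``per_day`` else per cycle."""
    if n0 <= 0 or nf <= 0:
        raise ValueError(f"densities must be positive (got n0={n0}, nf={nf})")
    m = float(np.log(nf / n0))
    return m / duration if per_day else m


def malthusian_table(records: pd.DataFrame, per_day: bool = False) -> pd.DataFrame:
    """Append a 'malthusian' column to a growth/density table.

    Expects columns population_id, treatment, condition, t0_cfu, t6_cfu and
    optionally duration_days (default 6).
    """
    missing = [c for c in GROWTH_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"growth table missing column(s): {missing}")
    bad = records.index[(records["t0_cfu"] <= 0) | (records["t6_cfu"] <= 0)]
    if len(bad):
        raise SchemaError(f"nonpositive density at row {bad[0]}")
    duration = records.get("duration_days", pd.Series(6.0, index=records.index))
    out = records.copy()
    m = np.log(records["t6_cfu"] / records["t0_cfu"])
    out["malthusian"] = m / duration if per_day else m
    return out


def growth_interaction_anova(records: pd.DataFrame, per_day: bool = False) -> pd.DataFrame:
    """Two-way ANOVA of Malthusian rates: treatment x growth-condition.

    Returns the ANOVA table (Type-I sums of squares; orders are equivalent on
    balanced data) with rows treatment, condition, treatment:condition,
    residual.
    """
    df = malthusian_table(records, per_day=per_day)
    cells = df.groupby(["treatment", "condition"]).size()
    n_t = df["treatment"].nunique()
    n_c = df["condition"].nunique()
    if n_t < 2 or n_c < 2:
        raise DesignError("two-way ANOVA needs >= 2 levels of each factor")
    if len(cells) < n_t * n_c:
        have = set(cells.index)
        empty = [
            (t, c)
            for t in df["treatment"].unique()
            for c in df["condition"].unique()
            if (t, c) not in have
        ]
        raise DesignError(f"empty treatment x condition cell(s): {empty}")
    fit = smf.ols("malthusian ~ C(treatment) * C(condition)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    table.index = ["treatment", "condition", "treatment:condition", "residual"]
    return table


def competition_oneway_anova(values, groups) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD on per-population competition outcomes.

    ``values`` are final relative abundances (or any response), ``groups``
    the treatment labels. Returns (anova_table, tukey_table); Tukey adjusted
    p-values use the studentized-range distribution with pooled within-group
    variance.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DesignError("one-way ANOVA needs >= 2 groups")
    by = [values[groups == g] for g in labels]
    if any(len(v) < 2 for v in by):
        raise DesignError("every group needs >= 2 values")
    if all(np.var(v, ddof=1) == 0 for v in by):
        raise DesignError("zero within-group variance in all groups: F is undefined")
    f, p = stats.f_oneway(*by)
    n = len(values)
    k = len(labels)
    grand = values.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in by)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by)
    anova = pd.DataFrame(
        {
            "sum_sq": [ssb, ssw],
            "df": [k - 1, n - k],
            "F": [f, np.nan],
            "PR(>F)": [p, np.nan],
        },
        index=["group", "residual"],
    )
    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return anova, tukey


def welch_anova(values, groups) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Does not assume equal group variances; the denominator df follow the
    Welch-Satterthwaite approximation. For two groups, F equals the squared
    Welch t statistic.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise DesignError("Welch's ANOVA needs >= 2 groups")
    by = [values[groups == g] for g in labels]
    ns = np.array([len(v) for v in by], dtype=float)
    if np.any(ns < 2):
        raise DesignError("every group needs >= 2 values")
    means = np.array([v.mean() for v in by])
    variances = np.array([v.var(ddof=1) for v in by])
    if np.any(variances == 0):
        raise DesignError(
            "zero within-group variance: Welch weights are undefined for that group"
        )
    w = ns / variances
    wsum = w.sum()
    grand = (w * means).sum() / wsum
    num = (w * (means - grand) ** 2).sum() / (k - 1)
    lam = ((1 - w / wsum) ** 2 / (ns - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = float(num / den)
    df1 = float(k - 1)
    df2 = float((k**2 - 1) / (3 * lam))
    p = float(stats.f.sf(f, df1, df2))
    return WelchAnovaResult(F=f, df1=df1, df2=df2, p=p)
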