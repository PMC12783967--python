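"""Group statistics over genotype × age result tables.

Implements the study's statistical toolkit: two-way ANOVA (type-II sums
of squares) with Bonferroni-corrected pairwise genotype contrasts
within age, the tie-corrected Kruskal–Wallis test used for noise power
comparisons, the unpaired two-tailed t test (computable from printed
summary statistics alone), a Z-score outlier filter, and mean ± SD (n)
summary-table rendering with significance stars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResults",
    "two_way_anova_bonferroni",
    "kruskal_wallis",
    "t_test_from_summary",
    "z_outlier_filter",
    "significance_stars",
    "render_summary_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary: mean ± SD with sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return cls(float(v.mean()), sd, len(v))


@dataclass
class AnovaResults:
    """Two-way ANOVA with Bonferroni-adjusted pairwise contrasts."""

    anova_table: pd.DataFrame  # per-effect sum_sq, df, F, PR(>F)
    pairwise: pd.DataFrame  # genotype contrast within each age level

    def effect(self, name: str) -> pd.Series:
        idx = [i for i in self.anova_table.index if name in i]
        if not idx:
            raise KeyError(name)
        return self.anova_table.loc[idx[0]]

    def summary(self) -> str:
        return (
            "Two-way ANOVA (type II)\n"
            + self.anova_table.to_string()
            + "\n\nPairwise contrasts (Bonferroni-adjusted)\n"
            + self.pairwise.to_string(index=False)
        )


def two_way_anova_bonferroni(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "age",
) -> AnovaResults:
    """Two-way ANOVA (type-II sums of squares, interaction included)
    with pairwise ``factor_a`` contrasts within each ``factor_b`` level,
    Bonferroni-adjusted by the number of contrasts.

    Requires at least 2 levels per factor and at least 2 observations in
    every factor-level cell; an empty cell raises an error naming it.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[value, factor_a, factor_b]].dropna().copy()
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    for la in levels_a:
        for lb in levels_b:
            n = ((df[factor_a] == la) & (df[factor_b] == lb)).sum()
            if n < 2:
                raise ValueError(
                    f"cell ({factor_a}={la}, {factor_b}={lb}) has {n} "
                    "observations; at least 2 required"
                )

    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = [
        str(i)
        .replace(f"C(Q('{factor_a}'))", factor_a)
        .replace(f"C(Q('{factor_b}'))", factor_b)
        for i in anova.index
    ]

    if len(levels_a) != 2:
        raise ValueError("pairwise contrasts assume exactly 2 genotype levels")
    rows = []
    n_contrasts = len(levels_b)
    for lb in levels_b:
        x = df.loc[(df[factor_a] == levels_a[0]) & (df[factor_b] == lb), value]
        y = df.loc[(df[factor_a] == levels_a[1]) & (df[factor_b] == lb), value]
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                factor_b: lb,
                "contrast": f"{levels_a[0]} vs {levels_a[1]}",
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(float(p) * n_contrasts, 1.0),
            }
        )
    return AnovaResults(anova, pd.DataFrame(rows))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with its chi-square p-value.

    All-identical data across groups yields (H = 0, p = 1).
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("each group needs at least 1 observation")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "welch"
) -> tuple[float, float, float]:
    """Unpaired two-tailed t test from group summaries.

    Returns ``(t, df, p)``; ``variant`` is ``"welch"`` (default) or
    ``"pooled"``.  Zero variance in both groups with equal means gives
    t = 0, p = 1.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            df = a.n + b.n - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    equal_var = variant == "pooled"
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        dof = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        dof = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(dof), float(res.pvalue)


def z_outlier_filter(values, threshold: float = 2.0) -> np.ndarray:
    """Single-pass Z-score outlier removal.

    Z-scores use the sample mean and SD (ddof=1) of all values; entries
    with |z| > threshold are dropped.  Needs n >= 3; zero SD removes
    nothing.  Note |z| is bounded by (n−1)/√n, so small samples can
    never exceed large thresholds.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return v.copy()
    z = (v - v.mean()) / sd
    return v[np.abs(z) <= threshold]


def significance_stars(p: float) -> str:
    """Star notation: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_summary_table(
    rows: pd.DataFrame,
    metrics,
    group_cols=("genotype", "age"),
    p_values: dict | None = None,
) -> pd.DataFrame:
    """Render per-metric "mean ± SD (n)" cells per genotype × age group.

    ``rows`` holds one observation per row with the metric columns and
    the grouping columns; ``p_values`` maps ``(metric, group)`` to a
    p-value whose significance stars are appended to the cell.  Missing
    groups render as an em-dash.
    """
    if rows.empty:
        raise ValueError("no observations to summarise")
    group_cols = list(group_cols)
    groups = (
        rows[group_cols].drop_duplicates().sort_values(group_cols).itertuples(
            index=False, name=None
        )
    )
    groups = list(groups)
    out = {}
    for metric in metrics:
        cells = []
        for g in groups:
            mask = np.logical_and.reduce(
                [rows[c] == v for c, v in zip(group_cols, g)]
            )
            vals = rows.loc[mask, metric].dropna()
            if vals.empty:
                cells.append("—")
                continue
            summ = GroupSummary.from_values(vals)
            cell = f"{summ.mean:.3g} ± {summ.sd:.3g} ({summ.n})"
            if p_values:
                p = p_values.get((metric, g))
                if p is not None:
                    cell += f" {significance_stars(p)}".rstrip()
            cells.append(cell)
        out[metric] = cells
    cols = pd.Index(
        [" ".join(str(v) for v in g) for g in groups], name="group"
    )
    return pd.DataFrame(out, index=cols).T
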