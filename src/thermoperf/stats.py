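"""Inferential layer: ANOVA with Tukey HSD, Levene's test, regressions.

Mirrors the study's statistical design:

* two-way ANOVA (temperature x acclimation status + interaction, type-II
  sums of squares) with Tukey HSD on cell means for performance metrics
  across the 14-2 degC range shared by acute and acclimated exposures;
* one-way ANOVA across the broader acute exposure range (26-2 degC);
* a one-way "sensitivity" ANOVA comparing the five interval-by-treatment
  levels of omnibus thermal sensitivity, with performance metrics as
  replicates;
* Levene's test (mean-centred absolute deviations) for homogeneity of
  variances;
* per-treatment OLS of total EPOC on exhaustive exercise effort over
  group means, with a pooled effort x treatment interaction model for
  the slope-difference test.

Significance is assessed at alpha = 0.05; no multiple-testing layer
beyond Tukey is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


class StatsError(ValueError):
    """Raised on degenerate statistical inputs."""


@dataclass
class AnovaResult:
    """Term table (factor, F, df, p) plus a Tukey pairwise table."""

    terms: pd.DataFrame
    tukey: pd.DataFrame | None = None

    def p_for(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])


@dataclass
class RegressionComparison:
    """Per-treatment OLS fits and the slope-difference (interaction) test."""

    per_group: pd.DataFrame  # treatment, slope, intercept, r_squared, p, n
    interaction_p: float
    slopes_differ: bool = field(init=False)

    def __post_init__(self) -> None:
        self.slopes_differ = self.interaction_p < ALPHA


def _clean_anova_table(tab: pd.DataFrame) -> pd.DataFrame:
    """Tidy a statsmodels ANOVA table; 0/0 F (no variance) becomes F=0, p=1."""
    tab = tab.reset_index().rename(
        columns={"index": "term", "PR(>F)": "p", "sum_sq": "ss"}
    )
    tab = tab[tab["term"] != "Residual"].copy()
    zero_ss = tab["ss"].abs() < 1e-12
    tab.loc[zero_ss, "F"] = 0.0
    tab.loc[zero_ss, "p"] = 1.0
    tab["F"] = tab["F"].fillna(0.0)
    tab["p"] = tab["p"].fillna(1.0)
    return tab[["term", "ss", "df", "F", "p"]]


def _tukey_table(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    res = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return frame.rename(
        columns={
            "group1": "group_1",
            "group2": "group_2",
            "meandiff": "difference",
            "p-adj": "p_adjusted",
        }
    )


def one_way_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "temperature",
    tukey: bool = True,
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD across the levels of one factor."""
    counts = table.groupby(group_col)[value_col].count()
    if len(counts) < 2 or (counts < 2).any():
        raise StatsError(
            f"one-way ANOVA needs >=2 groups with >=2 observations; "
            f"counts: {counts.to_dict()}"
        )
    data = table.rename(columns={value_col: "y", group_col: "g"})
    model = smf.ols("y ~ C(g)", data=data).fit()
    terms = _clean_anova_table(anova_lm(model, typ=2))
    terms["term"] = terms["term"].replace({"C(g)": group_col})
    tukey_tab = None
    if tukey and terms["F"].iloc[0] > 0:
        tukey_tab = _tukey_table(
            data["y"].to_numpy(float), data["g"].astype(str).to_numpy()
        )
    return AnovaResult(terms=terms, tukey=tukey_tab)


def two_way_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    factor_a: str = "temperature",
    factor_b: str = "treatment",
    tukey: bool = True,
) -> AnovaResult:
    """Two-way ANOVA (A, B, A:B; type-II SS) with Tukey HSD on cell means.

    Type-II sums of squares tolerate the mild imbalance of field group
    sizes.  Empty cells are an error naming the cells.
    """
    cells = table.groupby([factor_a, factor_b])[value_col].count()
    full = pd.MultiIndex.from_product(
        [table[factor_a].unique(), table[factor_b].unique()]
    )
    empty = sorted(set(full) - set(cells[cells >= 2].index))
    if empty:
        raise StatsError(f"cells with <2 observations: {empty}")
    data = table.rename(
        columns={value_col: "y", factor_a: "a", factor_b: "b"}
    )
    model = smf.ols("y ~ C(a) * C(b)", data=data).fit()
    terms = _clean_anova_table(anova_lm(model, typ=2))
    terms["term"] = terms["term"].replace(
        {
            "C(a)": factor_a,
            "C(b)": factor_b,
            "C(a):C(b)": f"{factor_a}:{factor_b}",
        }
    )
    tukey_tab = None
    if tukey and terms["F"].abs().sum() > 0:
        labels = (
            data["a"].astype(str) + ":" + data["b"].astype(str)
        ).to_numpy()
        tukey_tab = _tukey_table(data["y"].to_numpy(float), labels)
    return AnovaResult(terms=terms, tukey=tukey_tab)


def sensitivity_anova(table: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA of omnibus sensitivity across interval-treatment levels.

    ``table`` holds one row per metric and level with columns ``level``
    (e.g. ``"acute 8-2"``) and ``value`` (the metric's Q10 or percent
    change for that interval); metrics are the replicates.
    """
    counts = table.groupby("level")["value"].count()
    if (counts < 2).any():
        raise StatsError(
            f"each interval-treatment level needs >=2 metrics; "
            f"counts: {counts.to_dict()}"
        )
    return one_way_anova(table, value_col="value", group_col="level")


def levene(groups: list[np.ndarray]) -> tuple[float, float]:
    """Levene's test of equality of variances (mean-centred).

    Returns (W, p).  W is the one-way ANOVA F statistic on the absolute
    deviations from each group's mean.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise StatsError("Levene's test needs >=2 groups with >=2 values")
    w, p = scipy.stats.levene(*groups, center="mean")
    return float(w), float(p)


def effort_epoc_regression(table: pd.DataFrame) -> RegressionComparison:
    """EPOC-vs-effort regressions per treatment and slope comparison.

    ``table`` columns: ``treatment``, ``effort`` (BL), ``epoc``
    (mg O2 kg^-1), one row per temperature (group means).  Each
    treatment needs >=3 temperature points.  The slope difference is the
    effort x treatment interaction in the pooled OLS model.
    """
    rows = []
    for treatment, grp in table.groupby("treatment"):
        if len(grp) < 3:
            raise StatsError(
                f"{treatment}: need >=3 temperature points, got {len(grp)}"
            )
        x = sm.add_constant(grp["effort"].to_numpy(float))
        fit = sm.OLS(grp["epoc"].to_numpy(float), x).fit()
        rows.append(
            {
                "treatment": treatment,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "r_squared": float(fit.rsquared),
                "p": float(fit.pvalues[1]),
                "n": int(len(grp)),
            }
        )
    pooled = smf.ols(
        "epoc ~ effort * C(treatment)", data=table
    ).fit()
    inter = [
        name
        for name in pooled.pvalues.index
        if name.startswith("effort:C(treatment)")
    ]
    if len(inter) != 1:
        raise StatsError("slope comparison requires exactly two treatments")
    return RegressionComparison(
        per_group=pd.DataFrame(rows),
        interaction_p=float(pooled.pvalues[inter[0]]),
    )
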