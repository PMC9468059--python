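"""Thin statistical reporting layer and figure-style plots.

Standard linear-model machinery (two-way ANOVA with Type-II sums of squares
for unbalanced designs, ANCOVA with a numeric covariate, Pearson correlation,
Tukey post-hoc) applied to pipeline outputs.  Nothing here is novel; the
functions exist so every test the pipeline reports has one documented entry
point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class StatReport:
    """One statistical test: per-term F, df, and p, plus group sizes."""

    name: str
    table: pd.DataFrame  # index: term; columns: F, df, p
    n: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _clean_anova(table: pd.DataFrame, n: int, name: str) -> StatReport:
    out = pd.DataFrame(
        {
            "F": table["F"],
            "df": table["df"],
            "p": table["PR(>F)"],
        }
    )
    out = out[out.index != "Residual"]
    # constant response: zero effect and residual SS makes F = 0/0; report
    # F = 0, p = 1 for the degenerate no-signal case
    degenerate = out["F"].isna()
    out.loc[degenerate, "F"] = 0.0
    out.loc[degenerate, "p"] = 1.0
    for col in ("F", "p"):
        if not np.all((out[col] >= 0) & (out[col] <= np.inf)):
            raise ValueError("singular design: invalid test statistics")
    return StatReport(name=name, table=out, n=n)


def two_way_anova(
    df: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = False,
) -> StatReport:
    """Two-way ANOVA main effects (Type-II SS; optional interaction term).

    Requires at least two levels per factor.  Raises on singular designs.
    """
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    op = "*" if interaction else "+"
    model = smf.ols(f"{value} ~ C({factor_a}) {op} C({factor_b})", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(model, typ=2)
    table = table.rename(
        index={f"C({factor_a})": factor_a, f"C({factor_b})": factor_b}
    )
    return _clean_anova(table, n=len(df), name="two_way_anova")


def ancova_age(
    df: pd.DataFrame, value: str, stage_col: str, age_col: str
) -> StatReport:
    """ANCOVA: factor plus numeric covariate in one linear model (Type-II SS)."""
    if not np.issubdtype(df[age_col].dtype, np.number):
        raise ValueError("covariate must be numeric")
    if df[age_col].std(ddof=0) == 0:
        raise ValueError("zero-variance covariate")
    if df[stage_col].nunique() < 2:
        raise ValueError("stage factor needs at least 2 levels")
    model = smf.ols(f"{value} ~ C({stage_col}) + {age_col}", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("collinear design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(model, typ=2)
    table = table.rename(index={f"C({stage_col})": stage_col})
    return _clean_anova(table, n=len(df), name="ancova")


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with t-based two-sided p (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r requires paired vectors with n >= 3")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        warnings.warn("zero variance: correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def one_way_anova_tukey(
    df: pd.DataFrame, value: str, group_col: str, alpha: float = 0.05
):
    """One-way ANOVA plus Tukey HSD post-hoc comparisons.

    Returns ``(StatReport, tukey_table)`` where the Tukey table is a
    DataFrame of pairwise comparisons.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    model = smf.ols(f"{value} ~ C({group_col})", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(model, typ=2)
    table = table.rename(index={f"C({group_col})": group_col})
    report = _clean_anova(table, n=len(df), name="one_way_anova")
    tukey = pairwise_tukeyhsd(df[value], df[group_col], alpha=alpha)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return report, tukey_df


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def _get_axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_group_bars(summary: pd.DataFrame, value: str, group_col: str, ax=None):
    """Bar plot of group means with SEM error bars (mean ± SEM convention)."""
    ax = _get_axes(ax)
    means = summary[f"{value}_mean"]
    sems = summary[f"{value}_sem"].fillna(0.0)
    ax.bar(summary[group_col].astype(str), means, yerr=sems, capsize=3)
    ax.set_ylabel(value)
    return ax


def plot_shell_profile(profile, ax=None, label: str | None = None):
    """Shell-fraction curve over concentric distance bands."""
    ax = _get_axes(ax)
    centres = 0.5 * (profile.shell_edges_um[:-1] + profile.shell_edges_um[1:])
    ax.plot(centres, profile.fractions, marker="o", label=label)
    ax.set_xlabel("distance from nearest cell body (μm)")
    ax.set_ylabel("process volume fraction")
    if label:
        ax.legend()
    return ax


def plot_nni_dots(df: pd.DataFrame, group_col: str = "braak_group", ax=None):
    """Per-case NNI dot plot with the clustering bound at 1.0."""
    ax = _get_axes(ax)
    groups = list(dict.fromkeys(df[group_col]))
    for i, g in enumerate(groups):
        vals = df.loc[df[group_col] == g, "nni"]
        ax.plot([i] * len(vals), vals, "o", alpha=0.7)
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xticks(range(len(groups)), [str(g) for g in groups])
    ax.set_ylabel("nearest-neighbour index")
    return ax


def save_figure(ax, path) -> None:
    ax.figure.savefig(path, bbox_inches="tight")
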