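"""Condition comparison and figure-style summaries.

Ties per-cell metrics to condition labels: two-sample Student's t-tests
(pooled variance, two-tailed; Welch behind a flag), per-condition summary
statistics, and box/violin plots drawn with the source convention — whiskers
at the full range, box at the interquartile range, center line at the
median. P-values are reported raw; Benjamini-Hochberg correction is an
opt-in extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "ttest_two_sample",
    "significance_label",
    "validate_condition_table",
    "summarize",
    "compare_conditions",
    "box_plot",
    "violin_plot",
]


@dataclass
class TestResult:
    metric_name: str
    condition_pair: tuple[str, str]
    t_statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    significance_label: str


def significance_label(p: float) -> str:
    """ns / * / ** / *** bands; *** means p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_two_sample(
    a,
    b,
    metric_name: str = "",
    condition_pair: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> TestResult:
    """Unpaired two-tailed Student's t-test (pooled variance).

    ``welch=True`` switches to the unequal-variance form. Errors on groups
    smaller than 2 or zero pooled variance (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not welch and a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        metric_name=metric_name,
        condition_pair=condition_pair,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
        significance_label=significance_label(float(res.pvalue)),
    )


def validate_condition_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format metric table contract.

    Required columns: cell_label, condition, metric_name, value. No duplicate
    (cell_label, condition, metric_name) rows; all values finite.
    """
    required = ["cell_label", "condition", "metric_name", "value"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"condition table missing columns: {missing}")
    key = ["cell_label", "condition", "metric_name"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (cell_label, condition, metric_name) rows")
    if not np.isfinite(table["value"]).all():
        raise ValueError("non-finite metric values in condition table")
    return table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-metric summary: min, Q1, median, Q3, max, n.

    Quantiles use linear interpolation (the inclusive convention, median-
    unbiased for small n), matching how the box plots are drawn.
    """
    validate_condition_table(table)
    if table.empty:
        raise ValueError("empty condition table")
    rows = []
    for (cond, metric), grp in table.groupby(["condition", "metric_name"]):
        v = grp["value"]
        rows.append(
            {
                "condition": cond,
                "metric_name": metric,
                "n": int(v.size),
                "min": float(v.min()),
                "q1": float(v.quantile(0.25)),
                "median": float(v.median()),
                "q3": float(v.quantile(0.75)),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)


def compare_conditions(
    table: pd.DataFrame,
    metric_name: str,
    pair: tuple[str, str],
    welch: bool = False,
    bh_correct: bool = False,
    all_p_values: list[float] | None = None,
) -> TestResult:
    """t-test one metric between two conditions from the long table."""
    validate_condition_table(table)
    sub = table[table["metric_name"] == metric_name]
    a = sub.loc[sub["condition"] == pair[0], "value"].to_numpy()
    b = sub.loc[sub["condition"] == pair[1], "value"].to_numpy()
    result = ttest_two_sample(a, b, metric_name, pair, welch=welch)
    if bh_correct and all_p_values:
        # opt-in Benjamini-Hochberg across the provided family of tests
        ps = np.asarray(sorted(all_p_values + [result.p_value]))
        rank = int(np.searchsorted(ps, result.p_value)) + 1
        adj = min(1.0, result.p_value * len(ps) / rank)
        log.info("BH-adjusted p for %s: %.3g (raw %.3g)", metric_name, adj, result.p_value)
    return result


def tests_to_dataframe(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric_name": r.metric_name,
                "condition_a": r.condition_pair[0],
                "condition_b": r.condition_pair[1],
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "n_a": r.n_per_group[0],
                "n_b": r.n_per_group[1],
                "significance": r.significance_label,
            }
            for r in results
        ]
    )


def box_plot(table: pd.DataFrame, metric_name: str, ax=None):
    """Box plot per condition: whiskers at range, box at IQR, line at median."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = table[table["metric_name"] == metric_name]
    conditions = sorted(sub["condition"].unique())
    data = [sub.loc[sub["condition"] == c, "value"].to_numpy() for c in conditions]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(len(conditions), 2) + 1, 3.5))
    ax.boxplot(data, tick_labels=conditions, whis=(0, 100), showfliers=False)
    ax.set_ylabel(metric_name)
    for i, v in enumerate(data, start=1):
        ax.annotate(f"n={len(v)}", (i, ax.get_ylim()[0]), ha="center",
                    xytext=(0, 4), textcoords="offset points", fontsize=8)
    return ax


def violin_plot(table: pd.DataFrame, metric_name: str = "u", ax=None):
    """Violin plot per condition — the radial-distribution view.

    Draws guide lines at u = ±0.5 (the thylakoid-peak positions) when the
    metric is a normalized radial coordinate.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = table[table["metric_name"] == metric_name]
    conditions = sorted(sub["condition"].unique())
    data = [sub.loc[sub["condition"] == c, "value"].to_numpy() for c in conditions]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(len(conditions), 2) + 1, 3.5))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(conditions) + 1), conditions)
    ax.set_ylabel(metric_name)
    if metric_name in ("u", "abs_u", "|u|"):
        for y in ((0.5, -0.5) if metric_name == "u" else (0.5,)):
            ax.axhline(y, ls="--", lw=0.8, color="0.4")
    return ax
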