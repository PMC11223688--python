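"""Fidelity and hypothesis-testing statistics for compression evaluation.

Compressed and uncompressed motility amplitudes are compared as scatter
points fitted through the origin (y = m x, slope m = sum(xy) / sum(x^2))
together with Pearson's r; dose/time responses are compared to their
pre-exposure baseline with the two-tailed unequal-variance (Welch) t-test.
Because multiplying one column of paired M values by a constant changes the
regression slope but neither Pearson's r nor any within-column t-test,
compression that merely rescales M preserves the pattern of significance
calls — the property the evaluation is designed to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ScatterFit:
    """Through-origin slope and Pearson correlation of a scatter plot.

    ``low_n`` flags a correlation computed from fewer than 3 points.
    """

    slope: float
    pearson_r: float
    n_points: int
    low_n: bool = False


@dataclass(frozen=True)
class TTestResult:
    """Welch t-test outcome: statistic, Welch-Satterthwaite df, two-tailed p.

    ``degenerate`` flags zero within-group variance in both groups, where the
    t statistic is a limit (0 for equal means, +/-inf otherwise).
    """

    t: float
    df: float
    p: float
    n_a: int
    n_b: int
    degenerate: bool = False


def slope_through_origin(x, y) -> float:
    """Least-squares slope of y = m x with no intercept: sum(xy) / sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 points")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all-zero x: through-origin slope undefined")
    return float(x @ y) / sxx


def pearson(x, y) -> float:
    """Product-moment correlation; constant input is an error, never 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def fit_scatter(x, y) -> ScatterFit:
    """Joint slope + Pearson summary of compressed-vs-uncompressed points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return ScatterFit(
        slope=slope_through_origin(x, y),
        pearson_r=pearson(x, y),
        n_points=x.size,
        low_n=x.size < 3,
    )


def welch_ttest(a, b) -> TTestResult:
    """Two-tailed heteroscedastic (Welch) two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # Limit of the t statistic as both variances vanish.
        if a.mean() == b.mean():
            return TTestResult(0.0, float(a.size + b.size - 2), 1.0, a.size, b.size, True)
        t = math.copysign(math.inf, a.mean() - b.mean())
        return TTestResult(t, float(a.size + b.size - 2), 0.0, a.size, b.size, True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
    )


def significance_stars(p: float, thresholds=(0.05, 0.01, 0.001)) -> str:
    """Asterisk flags: one star per threshold the p-value falls below."""
    return "*" * sum(p < t for t in sorted(thresholds, reverse=True))


def condition_table(
    data: pd.DataFrame,
    baseline: dict,
    *,
    value_col: str = "M",
    condition_cols: tuple[str, ...] = ("dose", "time"),
    method_col: str | None = "method",
    thresholds=(0.05, 0.01, 0.001),
) -> pd.DataFrame:
    """Per-condition mean, standard error and Welch p-value against baseline.

    ``data`` is long-format with one row per spheroid; ``baseline`` maps
    condition columns to the values identifying the pre-exposure group (e.g.
    ``{"time": "before"}``).  When ``method_col`` is present the table is
    computed in parallel for each compression method, so significance calls
    can be compared across methods.  p-values are raw (no multiple-testing
    correction); asterisk flags use the given thresholds.
    """
    for col in (*condition_cols, value_col):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if method_col is not None and method_col not in data.columns:
        method_col = None

    rows = []
    for method, sub in (
        data.groupby(method_col) if method_col else [(None, data)]
    ):
        base_mask = np.ones(len(sub), dtype=bool)
        for col, val in baseline.items():
            base_mask &= (sub[col] == val).to_numpy()
        base = sub.loc[base_mask, value_col].to_numpy()
        if base.size < 2:
            raise ValueError(f"baseline group has {base.size} spheroids; need >= 2")
        for cond, grp in sub.groupby(list(condition_cols)):
            vals = grp[value_col].to_numpy()
            if vals.size < 2:
                raise ValueError(f"condition {cond} has {vals.size} spheroids; need >= 2")
            test = welch_ttest(vals, base)
            row = dict(zip(condition_cols, cond if isinstance(cond, tuple) else (cond,)))
            if method_col:
                row[method_col] = method
            row.update(
                n=int(vals.size),
                mean=float(vals.mean()),
                sem=float(vals.std(ddof=1) / math.sqrt(vals.size)),
                t=test.t,
                p=test.p,
                stars=significance_stars(test.p, thresholds),
            )
            rows.append(row)
    return pd.DataFrame(rows)
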