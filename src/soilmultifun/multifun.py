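"""Ecosystem-multifunctionality statistics.

Two complementary summaries of a plot x function table are implemented:

* **Averaging approach** — each function is min-max standardised to
  [0, 1] across the analysed plots and the plot's multifunctionality is
  the arithmetic mean of its standardised functions.
* **Multiple-threshold approach** — for a threshold t (percent of the
  maximum observed value of each function), count the functions at or
  above t; across thresholds 1..99 the slope of this count against
  ln(sown richness) profiles how diversity effects fade as the
  performance bar rises.

A third summary treats the four standardised functions like species and
computes the Shannon diversity and evenness of the function "community",
quantifying how evenly a plot delivers its functions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDesignError,
    DegenerateFunctionError,
    InvalidThresholdError,
)

__all__ = [
    "standardize_functions",
    "average_multifunctionality",
    "threshold_counts",
    "threshold_slope_profile",
    "function_evenness",
    "multifunctionality_table",
]

log = logging.getLogger(__name__)

N_FUNCTIONS_LOG = np.log(4.0)  # evenness denominator for four functions


def standardize_functions(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max standardise each function column to [0, 1].

    Minima and maxima are taken over the rows of ``table`` (the analysed
    plot set), once across all treatments. Missing cells propagate.
    """
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        lo, hi = x.min(), x.max()
        if not np.isfinite(lo) or hi <= lo:
            raise DegenerateFunctionError(f"function {col!r} has no variation")
        out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


def average_multifunctionality(std: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the standardised functions per plot.

    Plots missing any function are excluded (complete-case) with a log
    message naming them.
    """
    complete = std.dropna()
    dropped = std.index.difference(complete.index)
    if len(dropped):
        log.info("average multifunctionality: excluded %d incomplete plots: %s",
                 len(dropped), list(dropped[:10]))
    return complete.mean(axis=1).rename("avg_multifunctionality")


def threshold_counts(table: pd.DataFrame, t: float) -> pd.Series:
    """Number of functions at or above t percent of each function's
    maximum observed raw value.

    ``t`` is a percentage in (0, 100]. Comparisons use ">=", so t = 100
    counts the functions whose maximum this plot attains.
    """
    if not 0 < t <= 100:
        raise InvalidThresholdError(f"threshold {t} outside (0, 100]")
    maxima = table.max(axis=0)
    cutoffs = (t / 100.0) * maxima
    counts = (table >= cutoffs).sum(axis=1)
    return counts.rename(f"count_t{t:g}")


def threshold_slope_profile(
    table: pd.DataFrame,
    richness: pd.Series,
    t_range=range(1, 100),
    regressor: str = "log",
) -> pd.DataFrame:
    """Slope of threshold-count on (log) sown richness, per threshold.

    For each t in ``t_range`` the per-plot count of functions at or above
    t% of maximum is regressed (OLS) on ln(richness) (or raw richness
    with ``regressor="linear"``). Returns a DataFrame with columns
    ``t``, ``slope``, ``se``.
    """
    r = richness.loc[table.index].astype(float)
    if r.nunique() < 2:
        raise DegenerateDesignError("need >= 2 distinct richness levels")
    if regressor == "log":
        x = np.log(r.to_numpy())
    elif regressor == "linear":
        x = r.to_numpy()
    else:
        raise ValueError(f"unknown regressor {regressor!r}")
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    n = len(x)
    rows = []
    for t in t_range:
        y = threshold_counts(table, t).to_numpy(dtype=float)
        slope = float(np.sum(xc * y) / sxx)
        resid = y - y.mean() - slope * xc
        mse = float(np.sum(resid**2)) / (n - 2)
        rows.append((t, slope, np.sqrt(mse / sxx)))
    return pd.DataFrame(rows, columns=["t", "slope", "se"])


def function_evenness(std: pd.DataFrame) -> pd.DataFrame:
    """Shannon diversity and evenness over a plot's standardised functions.

    Treating the functions like species: ``q_f = std_f / sum(std)``,
    ``H = -sum q_f ln q_f`` and evenness ``H / ln(n_functions)``. A plot
    whose standardised functions are all zero has evenness 0 (the empty
    community convention).
    """
    values = std.to_numpy(dtype=float)
    n_func = values.shape[1]
    h = np.zeros(len(values))
    for i, row in enumerate(values):
        total = row.sum()
        if not np.isfinite(total):
            h[i] = np.nan
            continue
        if total <= 0:
            h[i] = 0.0
            continue
        q = row[row > 0] / total
        h[i] = -np.sum(q * np.log(q))
    return pd.DataFrame(
        {"H_func": h, "evenness_func": h / np.log(n_func)}, index=std.index
    )


def multifunctionality_table(
    table: pd.DataFrame, focal_thresholds=(20, 40, 60, 80)
) -> pd.DataFrame:
    """Per-plot multifunctionality summary used by the pipeline.

    Columns: average multifunctionality, threshold counts at the focal
    thresholds, and Shannon diversity/evenness of functions. Rows with
    any missing function carry NaN in every derived column.
    """
    complete = table.dropna()
    std = standardize_functions(complete)
    out = pd.DataFrame(index=table.index)
    out["avg_multifunctionality"] = average_multifunctionality(std)
    for t in focal_thresholds:
        out[f"count_t{t:g}"] = threshold_counts(complete, t)
    ev = function_evenness(std)
    out["H_func"] = ev["H_func"]
    out["evenness_func"] = ev["evenness_func"]
    return out
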