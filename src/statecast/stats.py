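"""Cohort-level statistics: paired method comparison and subgroup analysis.

The per-individual metrics table (one row per individual x model x gap x
mode) feeds two analyses:

* ``compare_methods`` — for each (model, gap, metric) cell, means and
  standard deviations per response mode over individuals plus a paired
  t-test on the per-individual differences d = original - transformed
  (negative t: the transformed mode is better).  An unpaired Welch variant
  is available.
* ``subgroup_analysis`` — whether performance depends on baseline
  covariates: one-way ANOVA across sex groups and, for the continuous
  covariates (age, weight, height), a simple linear regression whose
  overall F-test equals the squared t of the slope.

Undefined per-individual metrics (NaN) are dropped pairwise; raw p-values
are reported, with an optional Benjamini–Hochberg adjustment helper.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import IncompleteExperimentError, InputError
from .pipeline import DEFAULT_GAPS, MODELS

COMPARISON_METRICS = ("auc", "f1", "sensitivity")
BASELINE_VARIABLES = ("sex", "age", "weight", "height")


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    degenerate: str | None = None  # reason when the test could not be run


def paired_t_test(x, y) -> TTestResult:
    """Two-sided paired t-test on d = x - y over complete pairs.

    Pairs with a missing value on either side are dropped.  Fewer than two
    complete pairs or zero difference variance are reported as degenerate
    (NaN statistics) rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and aligned by individual")
    mask = np.isfinite(x) & np.isfinite(y)
    d = x[mask] - y[mask]
    n = d.size
    if n < 2:
        return TTestResult(math.nan, math.nan, n, degenerate="insufficient_pairs")
    if np.ptp(d) == 0.0:
        return TTestResult(math.nan, math.nan, n, degenerate="zero_variance")
    res = sps.ttest_1samp(d, 0.0)
    return TTestResult(float(res.statistic), float(res.pvalue), n)


def welch_t_test(x, y) -> TTestResult:
    """Unpaired Welch alternative for the method comparison."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    n = min(x.size, y.size)
    if x.size < 2 or y.size < 2:
        return TTestResult(math.nan, math.nan, n, degenerate="insufficient_pairs")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        return TTestResult(math.nan, math.nan, n, degenerate="zero_variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue), n)


def compare_methods(
    metrics: pd.DataFrame,
    metric_names: Sequence[str] = COMPARISON_METRICS,
    models: Sequence[str] | None = None,
    gaps: Sequence[int] | None = None,
    paired: bool = True,
) -> pd.DataFrame:
    """Original-vs-transformed comparison per (model, gap, metric).

    Means/sds are computed over the complete-pair individuals so they match
    the t-test population.  Raises if any (model, gap) cell misses a mode.
    """
    if models is None:
        models = [m for m in MODELS if m in set(metrics["model"])]
    if gaps is None:
        gaps = sorted(set(metrics["gap"]))
    rows = []
    for model in models:
        for gap in gaps:
            cell = metrics[(metrics["model"] == model) & (metrics["gap"] == gap)]
            ori = cell[cell["mode"] == "original"].set_index("individual_id")
            tra = cell[cell["mode"] == "transformed"].set_index("individual_id")
            if ori.empty or tra.empty:
                raise IncompleteExperimentError(
                    f"missing mode for model={model!r}, gap={gap}"
                )
            common = ori.index.intersection(tra.index)
            for metric in metric_names:
                xo = ori.loc[common, metric].to_numpy(dtype=float)
                xt = tra.loc[common, metric].to_numpy(dtype=float)
                mask = np.isfinite(xo) & np.isfinite(xt)
                xo, xt = xo[mask], xt[mask]
                res = paired_t_test(xo, xt) if paired else welch_t_test(xo, xt)
                rows.append(
                    {
                        "model": model,
                        "gap": gap,
                        "metric": metric,
                        "ori_mean": float(np.mean(xo)) if xo.size else math.nan,
                        "ori_sd": float(np.std(xo, ddof=1)) if xo.size > 1 else math.nan,
                        "tra_mean": float(np.mean(xt)) if xt.size else math.nan,
                        "tra_sd": float(np.std(xt, ddof=1)) if xt.size > 1 else math.nan,
                        "t": res.t,
                        "p": res.p,
                        "n_pairs": res.n,
                        "degenerate": res.degenerate,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroup analysis


def anova_f(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p with the constant-response case defined as F=0."""
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def regression_f(x, y) -> tuple[float, float, float]:
    """Overall F-test of a simple linear regression; returns (F, p, slope).

    F equals the squared t-statistic of the slope.  A constant response is
    defined as F=0, slope 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0, 1.0, 0.0
    res = sps.linregress(x, y)
    if res.stderr == 0.0:
        return math.inf, 0.0, float(res.slope)
    t = res.slope / res.stderr
    return float(t * t), float(res.pvalue), float(res.slope)


def subgroup_analysis(
    metrics: pd.DataFrame,
    baselines: pd.DataFrame,
    model: str = "xgboost",
    mode: str = "transformed",
    metric_names: Sequence[str] = COMPARISON_METRICS,
    variables: Sequence[str] = BASELINE_VARIABLES,
    gaps: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Test baseline influence on per-individual performance.

    One row per variable x metric x gap for the selected (model, mode) cell.
    Sex uses one-way ANOVA (with per-group means reported); continuous
    variables use the regression F-test with the fitted slope.  A sex group
    with fewer than two members is reported as degenerate, not raised.
    """
    cell = metrics[(metrics["model"] == model) & (metrics["mode"] == mode)]
    if cell.empty:
        raise IncompleteExperimentError(f"no metrics for model={model!r}, mode={mode!r}")
    if gaps is None:
        gaps = sorted(set(cell["gap"]))
    merged = cell.merge(baselines, on="individual_id", how="inner")
    rows = []
    for gap in gaps:
        sub = merged[merged["gap"] == gap]
        for metric in metric_names:
            for var in variables:
                data = sub[[metric, var]].dropna()
                row = {
                    "variable": var,
                    "metric": metric,
                    "gap": gap,
                    "F": math.nan,
                    "p": math.nan,
                    "n": len(data),
                    "slope": math.nan,
                    "mean_male": math.nan,
                    "mean_female": math.nan,
                    "degenerate": None,
                }
                if var == "sex":
                    male = data.loc[data[var] == "male", metric].to_numpy(dtype=float)
                    female = data.loc[data[var] == "female", metric].to_numpy(dtype=float)
                    if male.size < 2 or female.size < 2:
                        row["degenerate"] = "group_too_small"
                    else:
                        f, p = anova_f([male, female])
                        row.update(
                            F=f, p=p,
                            mean_male=float(np.mean(male)),
                            mean_female=float(np.mean(female)),
                        )
                else:
                    if len(data) < 3:
                        row["degenerate"] = "group_too_small"
                    else:
                        f, p, slope = regression_f(
                            data[var].to_numpy(dtype=float),
                            data[metric].to_numpy(dtype=float),
                        )
                        row.update(F=f, p=p, slope=slope)
                rows.append(row)
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out
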