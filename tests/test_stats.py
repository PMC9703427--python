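"""Cohort statistics: paired t, ANOVA/regression F, and the comparison table."""

import math

import numpy as np
import pandas as pd
import pytest

import statecast as sc
from statecast.errors import IncompleteExperimentError


def hand_paired_t(d):
    """Closed-form oracle: t = mean(d) / (sd(d)/sqrt(n))."""
    d = np.asarray(d, float)
    n = d.size
    return d.mean() / (d.std(ddof=1) / math.sqrt(n))


def hand_anova_f(*groups):
    """Closed-form one-way ANOVA oracle from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in map(np.asarray, groups))
    ssw = sum(((np.asarray(g) - np.asarray(g).mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    return (ssb / df_b) / (ssw / df_w)


def test_paired_t_against_hand_oracle():
    x = np.array([0.9, 0.8, 0.7])
    y = np.array([0.85, 0.70, 0.68])
    res = sc.paired_t_test(x, y)
    assert res.t == pytest.approx(hand_paired_t(x - y), abs=1e-9)
    assert res.t == pytest.approx(2.4286, abs=1e-4)
    assert res.n == 3 and res.degenerate is None


def test_paired_t_antisymmetry():
    rng = np.random.default_rng(3)
    x, y = rng.random(20), rng.random(20)
    a, b = sc.paired_t_test(x, y), sc.paired_t_test(y, x)
    assert a.t == pytest.approx(-b.t) and a.p == pytest.approx(b.p)


def test_paired_t_degenerate_cases():
    x = np.array([0.5, 0.6, 0.7])
    assert sc.paired_t_test(x, x).degenerate == "zero_variance"
    assert sc.paired_t_test(x[:1], x[:1]).degenerate == "insufficient_pairs"
    # NaNs drop pairwise
    res = sc.paired_t_test(
        np.array([0.9, np.nan, 0.7, 0.6]), np.array([0.8, 0.5, np.nan, 0.5])
    )
    assert res.n == 2


def test_anova_against_hand_oracle():
    g1, g2 = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
    f, p = sc.anova_f([g1, g2])
    assert f == pytest.approx(13.5, abs=1e-9)
    assert f == pytest.approx(hand_anova_f(g1, g2), abs=1e-9)


def test_anova_constant_response_is_zero():
    f, p = sc.anova_f([np.full(5, 0.7), np.full(4, 0.7)])
    assert f == 0.0 and p == 1.0


def test_two_group_anova_equals_squared_pooled_t():
    rng = np.random.default_rng(8)
    g1, g2 = rng.random(12), rng.random(15) + 0.2
    f, p_f = sc.anova_f([g1, g2])
    from scipy import stats as sps

    t, p_t = sps.ttest_ind(g1, g2, equal_var=True)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p_f == pytest.approx(p_t, rel=1e-10)


def test_regression_f_equals_squared_slope_t():
    rng = np.random.default_rng(9)
    x = rng.uniform(20, 80, 40)
    y = 0.5 + 0.002 * x + rng.standard_normal(40) * 0.05
    f, p, slope = sc.regression_f(x, y)
    from scipy import stats as sps

    lr = sps.linregress(x, y)
    assert f == pytest.approx((lr.slope / lr.stderr) ** 2, rel=1e-10)
    assert p == pytest.approx(lr.pvalue, rel=1e-10)
    assert slope == pytest.approx(lr.slope)


def _toy_metrics_table(rng, n_ind=10, models=("logistic",), gaps=(1, 5), delta=0.0):
    rows = []
    for model in models:
        for gap in gaps:
            base = rng.uniform(0.6, 0.9, n_ind)
            for i in range(n_ind):
                for mode, off in (("original", 0.0), ("transformed", delta)):
                    rows.append(
                        {
                            "individual_id": f"P{i:02d}",
                            "model": model,
                            "gap": gap,
                            "mode": mode,
                            "auc": base[i] + off + rng.normal(0, 0.01),
                            "f1": base[i] + off + rng.normal(0, 0.01),
                            "sensitivity": base[i] + off + rng.normal(0, 0.01),
                            "specificity": 0.9,
                            "precision": 0.8,
                        }
                    )
    return pd.DataFrame(rows)


def test_compare_methods_layout_and_sign():
    rng = np.random.default_rng(10)
    table = _toy_metrics_table(rng, delta=0.05)  # transformed clearly better
    comp = sc.compare_methods(table)
    assert len(comp) == 1 * 2 * 3  # models x gaps x metrics
    assert (comp["tra_mean"] > comp["ori_mean"]).all()
    assert (comp["t"] < 0).all()  # d = ori - tra negative when tra better
    assert (comp["p"] < 0.05).all()
    assert (comp["n_pairs"] == 10).all()


def test_compare_methods_identical_modes_degenerate():
    rng = np.random.default_rng(11)
    table = _toy_metrics_table(rng, delta=0.0)
    # make transformed an exact copy of original
    piv = table[table["mode"] == "original"].copy()
    piv["mode"] = "transformed"
    comp = sc.compare_methods(pd.concat([table[table["mode"] == "original"], piv]))
    assert (comp["degenerate"] == "zero_variance").all()
    assert (comp["ori_mean"] == comp["tra_mean"]).all()


def test_compare_methods_missing_mode_raises():
    rng = np.random.default_rng(12)
    table = _toy_metrics_table(rng)
    with pytest.raises(IncompleteExperimentError):
        sc.compare_methods(table[table["mode"] == "original"])


def _toy_subgroup_inputs(rng, n=40, sex_gap=0.0, age_slope=0.0):
    ids = [f"P{i:02d}" for i in range(n)]
    sexes = np.where(np.arange(n) % 2 == 0, "male", "female")
    ages = rng.uniform(18, 90, n)
    auc = 0.8 + sex_gap * (sexes == "male") + age_slope * ages + rng.normal(0, 0.02, n)
    metrics = pd.DataFrame(
        {
            "individual_id": ids,
            "model": "xgboost",
            "gap": 5,
            "mode": "transformed",
            "auc": auc,
            "f1": auc,
            "sensitivity": auc,
        }
    )
    baselines = pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sexes,
            "age": ages,
            "weight": rng.normal(75, 15, n),
            "height": rng.normal(170, 10, n),
        }
    )
    return metrics, baselines


def test_subgroup_analysis_detects_planted_effects():
    rng = np.random.default_rng(13)
    metrics, baselines = _toy_subgroup_inputs(rng, sex_gap=0.05, age_slope=0.001)
    out = sc.subgroup_analysis(metrics, baselines)
    assert len(out) == 4 * 3 * 1  # variables x metrics x gaps
    sex_row = out[(out.variable == "sex") & (out.metric == "auc")].iloc[0]
    assert sex_row["p"] < 0.01
    assert sex_row["mean_male"] > sex_row["mean_female"]
    age_row = out[(out.variable == "age") & (out.metric == "auc")].iloc[0]
    assert age_row["p"] < 0.01 and age_row["slope"] > 0
    # no effect planted on height: typically non-significant, always defined
    height_row = out[(out.variable == "height") & (out.metric == "auc")].iloc[0]
    assert np.isfinite(height_row["F"])


def test_subgroup_constant_metric_gives_zero_f():
    rng = np.random.default_rng(14)
    metrics, baselines = _toy_subgroup_inputs(rng)
    for col in ("auc", "f1", "sensitivity"):
        metrics[col] = 0.75
    out = sc.subgroup_analysis(metrics, baselines)
    assert (out["F"] == 0.0).all()


def test_subgroup_small_group_degenerate():
    rng = np.random.default_rng(15)
    metrics, baselines = _toy_subgroup_inputs(rng)
    baselines["sex"] = ["male"] + ["female"] * (len(baselines) - 1)
    out = sc.subgroup_analysis(metrics, baselines)
    sex_rows = out[out.variable == "sex"]
    assert (sex_rows["degenerate"] == "group_too_small").all()


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.02, 0.03, 0.5, 0.9])
    adj = sc.benjamini_hochberg(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)
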