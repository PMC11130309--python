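"""Myeloid classing, ratio covariate, ROC, Kaplan-Meier, Cox."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from tamscreen import cohort, simulate
from tamscreen.cohort import (
    MyeloidClassRule,
    classify_myeloid,
    cox_univariate,
    km_logrank,
    ratio_statistic,
    roc_auc,
    stratify_quartile,
)


def brute_force_auc(pos, neg):
    """Oracle: count concordant pairs, ties worth 1/2."""
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def hand_logrank(times, events, groups):
    """Oracle: spreadsheet-style two-group log-rank computation."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    labels = np.unique(g)
    observed = expected = variance = 0.0
    for ti in sorted(set(t[e == 1])):
        at_risk = t >= ti
        n = at_risk.sum()
        n1 = (at_risk & (g == labels[0])).sum()
        d = ((t == ti) & (e == 1)).sum()
        d1 = ((t == ti) & (e == 1) & (g == labels[0])).sum()
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (observed - expected) ** 2 / variance


# ---------------------------------------------------------------------------
# myeloid classing and ratio
# ---------------------------------------------------------------------------

def _expr(rows):
    return pd.DataFrame(rows, columns=["C5AR1", "CD86", "CD163", "MRC1"],
                        index=[f"c{i}" for i in range(len(rows))]).astype(float)


def test_classify_precedence_and_exclusions():
    expr = _expr([
        [2.0, 9.0, 0.0, 0.0],   # C5AR1 detected -> C5aR1hi despite high CD86
        [0.0, 9.0, 0.0, 0.0],   # high CD86, exclusions absent -> CD86hi
        [0.0, 9.0, 1.0, 0.0],   # CD163 detected -> other
        [0.0, 0.5, 0.0, 0.0],   # CD86 below the top-25% cut -> other
        [0.0, 0.0, 0.0, 0.0],
    ])
    cls = classify_myeloid(expr)
    assert cls.tolist() == ["C5aR1hi", "CD86hi", "other", "other", "other"]


def test_classify_requires_rule_genes():
    with pytest.raises(ValueError, match="missing"):
        classify_myeloid(pd.DataFrame({"C5AR1": [1.0]}))


def test_classify_detected_mode():
    expr = _expr([[0.0, 0.5, 0.0, 0.0]])
    cls = classify_myeloid(expr, MyeloidClassRule(high_mode="detected"))
    assert cls.tolist() == ["CD86hi"]


def test_ratio_statistic_rules():
    assert ratio_statistic(10, 5, pseudocount=0) == pytest.approx(2.0)
    assert ratio_statistic(3, 0, pseudocount=1) == pytest.approx(4.0)
    # monotonicity
    assert ratio_statistic(5, 3) > ratio_statistic(4, 3)
    assert ratio_statistic(5, 4) < ratio_statistic(5, 3)
    with pytest.raises(ValueError):
        ratio_statistic(-1, 2)
    with pytest.raises(ZeroDivisionError):
        ratio_statistic(1, 0, pseudocount=0)


def test_quartile_stratification():
    g = stratify_quartile(pd.Series(np.arange(1.0, 9.0)))
    assert g.attrs["n_high"] == 2 and (g[-2:] == "high").all()

    g4 = stratify_quartile(pd.Series([1.0, 2.0, 3.0, 4.0]))
    assert g4.attrs["n_high"] == 1

    ranks = pd.Series([3.0, 1.0, 10.0, 2.0, 7.0, 5.0, 9.0, 4.0])
    a = stratify_quartile(ranks)
    b = stratify_quartile(np.exp(ranks))  # monotone transform
    assert (a == b.to_numpy()).all()

    with pytest.warns(UserWarning, match="identical"):
        deg = stratify_quartile(pd.Series([2.0] * 6))
    assert (deg == "high").all()


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_auc_perfect_separation_and_pair_oracle():
    auc, _ = roc_auc([3.0, 4.0, 1.0, 2.0], ["NE", "NE", "E", "E"])
    assert auc == pytest.approx(1.0)

    rng = np.random.default_rng(0)
    for n in (8, 15, 50):
        scores = np.round(rng.normal(size=n), 1)  # rounded -> ties occur
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        auc, p = roc_auc(scores, y, positive=True)
        oracle = brute_force_auc(scores[y], scores[~y])
        assert auc == pytest.approx(oracle, abs=1e-12)
        assert 0 <= p <= 1

    with pytest.raises(ValueError, match="both outcome classes"):
        roc_auc([1.0, 2.0], ["E", "E"])


def test_auc_label_permutation_centers_at_half():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=30)
    y = np.array(["NE"] * 12 + ["E"] * 18)
    aucs = []
    for _ in range(200):
        perm = rng.permutation(30)
        aucs.append(roc_auc(scores, y[perm])[0])
    assert abs(np.mean(aucs) - 0.5) < 0.02


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    times = [5.0, 8.0, 12.0, 20.0] * 2
    events = [1, 1, 0, 1] * 2
    groups = ["a"] * 4 + ["b"] * 4
    curves, chi2, p = km_logrank(times, events, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert curves["a"].iloc[0, 0] == pytest.approx(1.0)  # S(0) = 1


def test_logrank_matches_hand_computation_on_toy():
    times = [6.0, 7.0, 10.0, 15.0, 4.0, 5.0, 8.0, 12.0]
    events = [1, 1, 0, 1, 1, 1, 1, 0]
    groups = ["g1"] * 4 + ["g2"] * 4
    _, chi2, _ = km_logrank(times, events, groups)
    assert chi2 == pytest.approx(hand_logrank(times, events, groups),
                                 abs=1e-10)


def test_logrank_invariant_to_time_rescaling():
    t = simulate.generate_cohort(40, seed=4).table
    g = stratify_quartile(t["ratio"])
    _, chi2_days, _ = km_logrank(t["time_days"], t["event"], g)
    _, chi2_years, _ = km_logrank(t["time_days"] / 365.25, t["event"], g)
    assert chi2_days == pytest.approx(chi2_years, rel=1e-9)


def test_km_requires_events_and_two_groups():
    with pytest.raises(ValueError, match="event"):
        km_logrank([1.0, 2.0], [0, 0], ["a", "b"])
    with pytest.raises(ValueError, match="two groups"):
        km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def test_cox_agrees_with_lifelines():
    import lifelines

    for seed in range(5):
        t = simulate.generate_cohort(80, seed=seed).table
        ours = cox_univariate(t["time_days"], t["event"],
                              t["standardized_ratio"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = lifelines.CoxPHFitter().fit(
                pd.DataFrame({"t": t["time_days"], "e": t["event"],
                              "x": t["standardized_ratio"]}), "t", "e")
        assert ours.beta == pytest.approx(ref.params_["x"], abs=1e-4)
        assert ours.se == pytest.approx(ref.standard_errors_["x"], rel=1e-3)
        assert ours.converged


def test_cox_reparameterization_identity():
    t = simulate.generate_cohort(100, seed=2).table
    x = t["standardized_ratio"].to_numpy()
    r1 = cox_univariate(t["time_days"], t["event"], x)
    r2 = cox_univariate(t["time_days"], t["event"], 10.0 * x)
    assert r2.beta == pytest.approx(r1.beta / 10.0, rel=1e-6)
    # per-unit hazard ratio is consistent
    assert np.exp(r2.beta * 10.0) == pytest.approx(r1.hazard_ratio, rel=1e-6)


def test_cox_detects_monotone_likelihood():
    # covariate perfectly ordered with event times: separation
    times = np.arange(1.0, 21.0)
    events = np.ones(20, int)
    x = np.arange(20.0)
    with pytest.warns(UserWarning, match="monotone"):
        res = cox_univariate(times, events, x)
    assert res.separated


def test_cox_preconditions():
    with pytest.raises(ValueError, match="constant"):
        cox_univariate([1.0, 2.0, 3.0], [1, 1, 1], [2.0, 2.0, 2.0])
    with pytest.raises(ValueError, match="2 events"):
        cox_univariate([1.0, 2.0, 3.0], [1, 0, 0], [1.0, 2.0, 3.0])


def test_cox_summary_table():
    t = simulate.generate_cohort(60, seed=1).table
    res = cox_univariate(t["time_days"], t["event"], t["standardized_ratio"])
    summ = res.summary()
    assert {"coef", "HR", "HR 95% CI low"} <= set(summ.columns)
    assert summ.loc["covariate", "HR"] == pytest.approx(np.exp(res.beta))


def test_end_to_end_directional_recovery():
    # positive generator coefficient: high-quartile group does worse and the
    # Cox hazard ratio on the ratio covariate exceeds 1
    params = simulate.CohortParams(log_hazard_coef=1.0)
    hr_above_1 = 0
    for seed in range(40):
        t = simulate.generate_cohort(80, params, seed=seed).table
        res = cox_univariate(t["time_days"], t["event"],
                             t["standardized_ratio"])
        hr_above_1 += res.hazard_ratio > 1.0
    assert hr_above_1 >= 39
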