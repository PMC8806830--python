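import numpy as np
import pandas as pd
import pytest
from scipy import stats

import irlpair as ir
from irlpair.evaluate import (
    YEAR_DAYS,
    _censoring_km,
    _step_left,
    cox_covariate_analysis,
    encode_clinical,
    km_estimate,
    logrank_test,
    risk_plot_data,
    time_dependent_auc,
)


def logrank_oracle(times, events, in_a):
    """Hypergeometric-moment observed-minus-expected chi-square (by hand)."""
    O = E = V = 0.0
    times, events, in_a = map(np.asarray, (times, events, in_a))
    for t in np.unique(times[events == 1]):
        at = times >= t
        n, n1 = at.sum(), (at & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in_a).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def brute_force_auc(scores, times, events, tau):
    """Weighted case-control pair count (independent of the vectorized path)."""
    gt, gv = _censoring_km(np.asarray(times, float), np.asarray(events, int))
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        if times[i] <= tau and events[i] == 1:
            w = 1.0 / _step_left(gt, gv, times[i])
            for j in range(n):
                if times[j] > tau:
                    num += w * (1.0 if scores[i] > scores[j]
                                else 0.5 if scores[i] == scores[j] else 0.0)
                    den += w
    return num / den


def test_km_worked_six_subject_example():
    curve = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
    np.testing.assert_allclose(curve.event_times, [1, 3, 4, 6])
    np.testing.assert_allclose(curve.survival, [5 / 6, 5 / 8, 5 / 12, 0.0])
    np.testing.assert_array_equal(curve.at_risk, [6, 4, 3, 1])
    np.testing.assert_allclose(curve.censor_marks, [2, 5])


def test_km_equals_empirical_without_censoring():
    rng = np.random.default_rng(0)
    t = rng.exponential(100, 60)
    curve = km_estimate(t, np.ones(60))
    for tt, s in zip(curve.event_times, curve.survival):
        assert s == pytest.approx((t > tt).mean(), abs=1e-12)


def test_km_no_events_is_flat_one():
    curve = km_estimate([5.0, 9.0, 2.0], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.at(100.0) == 1.0


def test_km_empty_group_errors():
    with pytest.raises(ValueError):
        km_estimate([], [])


def test_logrank_identical_groups_is_zero():
    t = [3.0, 5.0, 7.0, 9.0]
    e = [1, 0, 1, 1]
    chi2, p = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_logrank_matches_hand_oracle():
    rng = np.random.default_rng(1)
    t = np.round(rng.exponential(50, 40), 1) + 1
    e = rng.integers(0, 2, 40)
    g = np.array(["a"] * 20 + ["b"] * 20)
    chi2, p = logrank_test(t, e, g)
    assert chi2 == pytest.approx(logrank_oracle(t, e, g == "a"), abs=1e-10)
    assert p == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-12)


def test_logrank_single_group_errors():
    with pytest.raises(ValueError, match="two groups"):
        logrank_test([1, 2], [1, 1], ["a", "a"])


def test_auc_perfect_marker_is_one():
    rng = np.random.default_rng(2)
    t = rng.uniform(10, 1000, 50)
    roc = time_dependent_auc(-t, t, np.ones(50), horizon=400.0)
    assert roc.auc == 1.0


def test_auc_null_marker_near_half():
    rng = np.random.default_rng(3)
    t = rng.exponential(500, 500)
    e = rng.uniform(size=500) < 0.7
    m = rng.normal(size=500)
    roc = time_dependent_auc(m, t, e.astype(int), horizon=365.0)
    assert 0.45 <= roc.auc <= 0.55


def test_auc_matches_brute_force_on_censored_toy():
    t = np.array([2, 5, 8, 3, 12, 20, 7, 15, 9, 30], dtype=float)
    e = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 0])
    m = np.array([2.0, 1.0, 1.5, 2.0, 0.5, -1.0, 0.8, 0.2, 1.5, -0.5])
    roc = time_dependent_auc(m, t, e, horizon=10.0)
    assert roc.auc == pytest.approx(brute_force_auc(m, t, e, 10.0), abs=1e-10)


def test_auc_equals_mann_whitney_without_censoring():
    rng = np.random.default_rng(4)
    t = rng.exponential(300, 80)
    m = -t + rng.normal(0, 100, 80)
    tau = float(np.median(t))
    roc = time_dependent_auc(m, t, np.ones(80, int), tau)
    case = t <= tau
    u = stats.mannwhitneyu(m[case], m[~case]).statistic
    assert roc.auc == pytest.approx(u / (case.sum() * (~case).sum()), abs=1e-12)


def test_auc_close_to_sksurv_reference():
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv
    rng = np.random.default_rng(5)
    n = 300
    m = rng.normal(size=n)
    t = rng.exponential(500 * np.exp(-0.7 * m))
    c = rng.exponential(900, n)
    time_, ev = np.minimum(t, c), t <= c
    y = Surv.from_arrays(ev, time_)
    ref, _ = cumulative_dynamic_auc(y, y, m, [365.0])
    mine = time_dependent_auc(m, time_, ev.astype(int), 365.0)
    assert mine.auc == pytest.approx(float(ref[0]), abs=0.01)


def test_auc_roc_grid_monotone(cohort, fitted, valid_pairs):
    prof = ir.compute_risk_scores(fitted["model"], valid_pairs)
    clin = cohort.clinical
    roc = time_dependent_auc(prof.loc[clin.index, "risk_score"],
                             clin["os_days"], clin["event"], 3 * YEAR_DAYS)
    assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()
    assert 0.0 <= roc.auc <= 1.0


def test_auc_requires_cases_and_controls():
    with pytest.raises(ValueError, match="no events"):
        time_dependent_auc([1, 2], [100, 200], [0, 0], 50.0)
    with pytest.raises(ValueError, match="past horizon"):
        time_dependent_auc([1, 2], [10, 20], [1, 1], 50.0)


def test_encode_clinical_levels(cohort):
    enc = encode_clinical(cohort.clinical)
    assert enc["t_stage"].between(1, 4).all()
    assert enc["stage"].between(1, 4).all()
    assert set(enc["sex"].unique()) <= {0, 1}


def test_cox_covariates_drop_constant_and_duplicate(cohort):
    clin = cohort.clinical.copy()
    clin["m_stage"] = "M0"                       # constant -> dropped
    clin["stage"] = clin["t_stage"].map({"T1": "I", "T2": "II", "T3": "III", "T4": "IV"})
    # stage now duplicates t_stage's numeric coding -> second copy dropped
    rng = np.random.default_rng(6)
    risk = pd.Series(rng.normal(size=len(clin)), index=clin.index)
    res = cox_covariate_analysis(clin, risk, mode="multivariate",
                                 covariates=("t_stage", "stage", "m_stage"))
    assert "m_stage" not in res.index
    assert "stage" not in res.index
    assert "t_stage" in res.index and "risk_score" in res.index


def test_risk_and_t_stage_independent_predictors():
    """With pair and T-stage effects both present, the multivariate model
    retains the risk score (and usually T stage) as independent."""
    risk_sig = stage_sig = 0
    reps = 15
    for s in range(reps):
        co = ir.generate_cohort(ir.default_config(seed=6000 + s))
        risk = co.truth.per_sample_linear_predictor
        res = cox_covariate_analysis(co.clinical, risk, mode="multivariate")
        risk_sig += res.loc["risk_score", "p"] < 0.05
        stage_sig += res.loc["t_stage", "p"] < 0.05
    assert risk_sig / reps >= 0.9
    assert stage_sig / reps >= 0.6


def test_cox_ci_brackets_estimate(cohort):
    risk = cohort.truth.per_sample_linear_predictor
    res = cox_covariate_analysis(cohort.clinical, risk, mode="univariate")
    assert ((res["ci_lo"] <= res["log_hr"]) & (res["log_hr"] <= res["ci_hi"])).all()
    assert (np.exp(res["log_hr"]) > 0).all()


def test_risk_plot_data_order_and_death_density(cohort, fitted, valid_pairs):
    prof = ir.compute_risk_scores(fitted["model"], valid_pairs)
    table = risk_plot_data(prof, cohort.clinical)
    assert (table["risk_score"].diff().dropna() >= 0).all()
    assert list(table["rank"]) == list(range(1, len(table) + 1))
    half = len(table) // 2
    low, high = table.iloc[:half], table.iloc[half:]
    assert high["event"].mean() > low["event"].mean()
    # cutoff index: the median sits at the boundary of the two halves
    med = table["risk_score"].median()
    assert low["risk_score"].iloc[-1] <= med <= high["risk_score"].iloc[0]
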