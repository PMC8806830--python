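import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import irlpair as ir
from irlpair.model import fit_multivariate_cox, lasso_select, univariate_cox_screen
from irlpair.pairs import PairIndicatorMatrix


def _clinical(times, events):
    idx = pd.Index([f"S{i:04d}-01" for i in range(len(times))], name="sample_id")
    return pd.DataFrame({"os_days": np.asarray(times, float),
                         "event": np.asarray(events, int)}, index=idx)


def _pm(ind: np.ndarray, clinical: pd.DataFrame, names=None):
    names = names or [f"A{i:03d}|B{i:03d}" for i in range(ind.shape[0])]
    return PairIndicatorMatrix(pd.DataFrame(
        ind.astype(np.int8), index=names, columns=clinical.index
    ))


def _ph_cohort(rng, betas, n, censor_scale=2500.0):
    """Exponential PH survival over Bernoulli(1/2) indicators."""
    p = len(betas)
    ind = rng.integers(0, 2, size=(p, n))
    lp = np.asarray(betas) @ ind
    t = rng.exponential(1300.0 * np.exp(-lp))
    c = rng.exponential(censor_scale, n)
    clinical = _clinical(np.round(np.minimum(t, c), 2) + 0.01, t <= c)
    return _pm(ind, clinical), clinical, ind


def test_split_464_even_and_event_balanced():
    co = ir.generate_cohort(ir.tcga_like_config(seed=4))
    train, test = ir.split_train_test(co.clinical.index, co.clinical, seed=1)
    assert {len(train), len(test)} == {232}
    e_train = co.clinical.loc[train, "event"].sum()
    e_test = co.clinical.loc[test, "event"].sum()
    assert abs(e_train - e_test) <= 1
    assert not set(train) & set(test)


def test_split_deterministic(cohort):
    a = ir.split_train_test(cohort.clinical.index, cohort.clinical, seed=9)
    b = ir.split_train_test(cohort.clinical.index, cohort.clinical, seed=9)
    assert a == b
    c = ir.split_train_test(cohort.clinical.index, cohort.clinical, seed=10)
    assert a != c


def test_split_rejects_bad_ratio(cohort):
    with pytest.raises(ValueError):
        ir.split_train_test(cohort.clinical.index, cohort.clinical, ratio=1.5)


def test_univariate_screen_power_on_true_pair():
    """A log(2) hazard pair at n=400 is retained with power >= 0.9."""
    rng = np.random.default_rng(123)
    kept = 0
    reps = 100
    for _ in range(reps):
        pm, clinical, _ = _ph_cohort(rng, [np.log(2)], n=400)
        candidates, _ = univariate_cox_screen(pm, clinical)
        kept += bool(candidates)
    assert kept / reps >= 0.9


def test_univariate_screen_strong_pair_dominates():
    """A pair that nearly separates survival has the smallest Wald p.

    (Separation is kept short of perfect: under complete separation the
    Wald statistic degenerates and its p-value is no longer extreme.)
    """
    rng = np.random.default_rng(5)
    n = 60
    ind = rng.integers(0, 2, size=(4, n))
    times = np.where(ind[0] == 1, rng.uniform(10, 350, n), rng.uniform(250, 900, n))
    clinical = _clinical(times, np.ones(n))
    pm = _pm(ind, clinical)
    _, table = univariate_cox_screen(pm, clinical)
    assert table["p"].idxmin() == pm.indicators.index[0]
    assert table["p"].min() < 1e-6


def test_univariate_screen_skips_constant_pairs():
    rng = np.random.default_rng(6)
    pm, clinical, _ = _ph_cohort(rng, [0.0, 0.0], n=120)
    ind = pm.indicators.copy()
    ind.iloc[0] = 1  # constant indicator cannot be scored
    pm2 = PairIndicatorMatrix(ind)
    _, table = univariate_cox_screen(pm2, clinical)
    assert pm2.indicators.index[0] not in table.index


def test_lasso_infinite_penalty_selects_nothing():
    rng = np.random.default_rng(7)
    pm, clinical, _ = _ph_cohort(rng, [0.8, -0.8], n=300)
    with pytest.raises(RuntimeError, match="zero"):
        lasso_select(pm, clinical, cv_folds=5, alphas=[1e6])


def test_lasso_zero_penalty_matches_unpenalized_support():
    rng = np.random.default_rng(8)
    pm, clinical, _ = _ph_cohort(rng, [0.9, -0.9], n=600)
    selected, lam, _ = lasso_select(pm, clinical, cv_folds=5, alphas=[1e-9])
    assert selected == list(pm.indicators.index)


def test_lasso_1se_rule_guards_null_data():
    """Under the 1-SE rule the pipeline almost never selects on null cohorts."""
    nonempty = 0
    reps = 10
    for s in range(reps):
        co = ir.generate_cohort(ir.null_config(seed=4000 + s))
        pm = ir.filter_valid_pairs(
            ir.build_pair_matrix(co.expression, co.truth.de_lnc_ids)
        )
        train, _ = ir.split_train_test(co.clinical.index, co.clinical, seed=s)
        try:
            ir.fit_signature(pm, co.clinical, train, seed=s, lambda_rule="1se")
            nonempty += 1
        except RuntimeError:
            pass
    assert nonempty / reps <= 0.1


def test_multivariate_single_pair_equals_univariate():
    rng = np.random.default_rng(9)
    pm, clinical, _ = _ph_cohort(rng, [0.7], n=300)
    _, table = univariate_cox_screen(pm, clinical, p_max=1.0)
    model = fit_multivariate_cox(pm, list(pm.indicators.index), clinical)
    assert model.coefficients[0] == pytest.approx(table["log_hr"].iloc[0], abs=1e-8)


def test_multivariate_drops_collinear_pairs():
    rng = np.random.default_rng(10)
    pm, clinical, ind = _ph_cohort(rng, [0.7], n=200)
    stacked = np.vstack([ind, ind[0], 1 - ind[0]])
    pm3 = _pm(stacked, clinical, names=["a|b", "dup|dup2", "comp|comp2"])
    model = fit_multivariate_cox(pm3, list(pm3.indicators.index), clinical)
    assert model.pairs == ["a|b"]


def test_signature_model_json_round_trip(tmp_path, fitted):
    p = tmp_path / "model.json"
    fitted["model"].to_json(p)
    back = ir.SignatureModel.from_json(p)
    assert back.pairs == fitted["model"].pairs
    np.testing.assert_allclose(back.coefficients, fitted["model"].coefficients)
    assert back.train_median_cutoff == fitted["model"].train_median_cutoff


def test_risk_score_empty_and_linearity():
    model = ir.SignatureModel(pairs=["a|b", "c|d"], coefficients=[0.5, -1.25],
                              train_median_cutoff=0.0)
    ind = pd.DataFrame([[0, 1], [0, 1]], index=["a|b", "c|d"], columns=["s1", "s2"])
    pm = PairIndicatorMatrix(ind.astype(np.int8))
    prof = ir.compute_risk_scores(model, pm, cutoff=0.0)
    assert prof.loc["s1", "risk_score"] == 0.0  # all-zero indicators
    assert prof.loc["s2", "risk_score"] == pytest.approx(0.5 - 1.25)
    # flipping one indicator moves the score by exactly that coefficient
    ind2 = ind.copy()
    ind2.loc["a|b", "s2"] = 0
    prof2 = ir.compute_risk_scores(model, PairIndicatorMatrix(ind2.astype(np.int8)),
                                   cutoff=0.0)
    assert prof.loc["s2", "risk_score"] - prof2.loc["s2", "risk_score"] == pytest.approx(0.5)


def test_risk_score_missing_pair_is_named():
    model = ir.SignatureModel(pairs=["a|b", "zz|ww"], coefficients=[0.5, 1.0],
                              train_median_cutoff=0.0)
    ind = pd.DataFrame([[0, 1]], index=["a|b"], columns=["s1", "s2"])
    with pytest.raises(KeyError, match="zz"):
        ir.compute_risk_scores(model, PairIndicatorMatrix(ind.astype(np.int8)))


def test_median_split_balance_with_distinct_scores():
    rng = np.random.default_rng(11)
    n_pairs, n = 16, 51
    ind = rng.integers(0, 2, size=(n_pairs, n))
    model = ir.SignatureModel(pairs=[f"a{i}|b{i}" for i in range(n_pairs)],
                              coefficients=rng.normal(size=n_pairs),
                              train_median_cutoff=0.0)
    pm = _pm(ind, _clinical(np.ones(n), np.ones(n)),
             names=model.pairs)
    prof = ir.compute_risk_scores(model, pm, cutoff="median")
    assert prof["risk_score"].nunique() == n  # distinct almost surely
    assert abs((prof["group"] == "high").sum() - (prof["group"] == "low").sum()) <= 1


def test_risk_scores_invariant_under_monotone_expression_transform(cohort, fitted):
    rng = np.random.default_rng(12)
    expr = cohort.expression
    vals = expr.values.to_numpy()
    a = rng.uniform(0.5, 2.0, size=vals.shape[1])
    transformed = ir.ExpressionMatrix(
        pd.DataFrame(np.exp(a * np.log1p(vals)) - 1, index=expr.values.index,
                     columns=expr.values.columns),
        expr.sample_class,
    )
    pm2 = ir.build_pair_matrix(transformed, cohort.truth.de_lnc_ids)
    prof1 = ir.compute_risk_scores(fitted["model"],
                                   ir.build_pair_matrix(expr, cohort.truth.de_lnc_ids))
    prof2 = ir.compute_risk_scores(fitted["model"], pm2)
    pd.testing.assert_frame_equal(prof1, prof2)


def test_six_pair_published_signature_structure():
    model = ir.six_pair_luad_model()
    assert len(model.pairs) == 6
    assert (model.coefficients > 0).sum() == 4
    assert (model.coefficients < 0).sum() == 2
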