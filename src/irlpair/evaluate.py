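"""Survival evaluation of a risk signature.

Kaplan-Meier curves and log-rank tests (via lifelines), time-dependent
ROC/AUC at fixed horizons under right censoring, and univariate /
multivariate Cox analyses of the risk score against clinical covariates.

The time-dependent AUC is the IPCW cumulative/dynamic estimator: cases are
subjects with an observed event by the horizon, controls are subjects
event-free past the horizon, and case contributions are weighted by the
inverse of the left limit of the censoring-distribution Kaplan-Meier
estimate at their event time (Uno-type weighting; ties in the marker
count 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import UNKNOWN, logger

#: days per year for the 1/3/5-year horizons
YEAR_DAYS = 365.25

T_STAGE_CODE = {"T1": 1, "T2": 2, "T3": 3, "T4": 4}
N_STAGE_CODE = {"N0": 0, "N1": 1, "N2": 2, "N3": 3}
M_STAGE_CODE = {"M0": 0, "M1": 1}
STAGE_CODE = {"I": 1, "II": 2, "III": 3, "IV": 4}
SEX_CODE = {"male": 1, "female": 0}


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) right-continuous step function."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_marks: np.ndarray

    def at(self, t: float) -> float:
        """S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate for one group (events-first at tied times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    km = KaplanMeierFitter().fit(times, events)
    tab = km.event_table.iloc[1:] if km.event_table.index[0] == 0 else km.event_table
    event_rows = tab[tab["observed"] > 0]
    sf = km.survival_function_["KM_estimate"]
    return SurvivalCurve(
        event_times=event_rows.index.to_numpy(dtype=float),
        survival=sf.loc[event_rows.index].to_numpy(dtype=float),
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        censor_marks=np.sort(times[events == 0]),
    )


def km_by_group(times, events, groups) -> dict:
    g = pd.Series(groups)
    return {
        level: km_estimate(np.asarray(times)[g.to_numpy() == level],
                           np.asarray(events)[g.to_numpy() == level])
        for level in g.unique()
    }


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    g = pd.Series(groups).astype(str)
    levels = g.unique()
    if len(levels) < 2:
        raise ValueError("log-rank test needs two groups")
    if len(levels) > 2:
        raise ValueError(f"expected two groups, got {len(levels)}")
    res = multivariate_logrank_test(np.asarray(times, float), g, np.asarray(events, int))
    return float(res.test_statistic), float(res.p_value)


def _censoring_km(times: np.ndarray, events: np.ndarray):
    """Reverse KM for the censoring distribution G(t).

    Deaths at a tied time are taken to precede censorings, so subjects dying
    at t remain in the censoring risk set at t.  Returns step-function arrays
    (times where G drops, G values after the drop).
    """
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    drop_t, g_vals = [], []
    g = 1.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        n_risk = n - i  # all with time >= t[i]
        n_cens = int((e[i:j] == 0).sum())
        if n_cens > 0:
            g *= 1.0 - n_cens / n_risk
            drop_t.append(t[i])
            g_vals.append(g)
        i = j
    return np.asarray(drop_t), np.asarray(g_vals)


def _step_left(ts: np.ndarray, ys: np.ndarray, t: float) -> float:
    """Left limit of a right-continuous step function starting at 1."""
    idx = np.searchsorted(ts, t, side="left") - 1
    return 1.0 if idx < 0 else float(ys[idx])


def _step_right(ts: np.ndarray, ys: np.ndarray, t: float) -> float:
    idx = np.searchsorted(ts, t, side="right") - 1
    return 1.0 if idx < 0 else float(ys[idx])


@dataclass
class TimeROC:
    horizon: float
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_cases: int
    n_controls: int


def time_dependent_auc(scores, times, events, horizon: float) -> TimeROC:
    """IPCW cumulative/dynamic AUC of a risk marker at ``horizon`` days."""
    m = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    case = (t <= horizon) & (e == 1)
    ctrl = t > horizon
    if case.sum() == 0:
        raise ValueError(f"no events by horizon {horizon}; AUC undefined")
    if ctrl.sum() == 0:
        raise ValueError(f"no event-free subjects past horizon {horizon}")
    gt, gv = _censoring_km(t, e)
    w = np.array([1.0 / _step_left(gt, gv, ti) for ti in t[case]])
    mc, mk = m[case], m[ctrl]
    cmp_ = (mc[:, None] > mk[None, :]).astype(float) + 0.5 * (mc[:, None] == mk[None, :])
    auc = float((w[:, None] * cmp_).sum() / (w.sum() * len(mk)))

    thresholds = np.unique(np.concatenate([mc, mk]))[::-1]
    tpr = np.array([(w * (mc > c)).sum() / w.sum() for c in thresholds])
    fpr = np.array([(mk > c).mean() for c in thresholds])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    return TimeROC(
        horizon=float(horizon), auc=auc, fpr=fpr, tpr=tpr,
        thresholds=thresholds, n_cases=int(case.sum()), n_controls=int(ctrl.sum()),
    )


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate encoding: ordinal stages, binary sex, continuous age.

    Unknown categories become NaN (handled per analysis).
    """
    out = pd.DataFrame(index=clinical.index)
    out["age"] = clinical["age"].astype(float)
    out["sex"] = clinical["sex"].map(SEX_CODE)
    out["t_stage"] = clinical["t_stage"].map(T_STAGE_CODE)
    out["n_stage"] = clinical["n_stage"].map(N_STAGE_CODE)
    out["m_stage"] = clinical["m_stage"].map(M_STAGE_CODE)
    out["stage"] = clinical["stage"].map(STAGE_CODE)
    return out


def cox_covariate_analysis(
    clinical: pd.DataFrame,
    risk_scores: pd.Series,
    mode: str = "univariate",
    covariates=("age", "sex", "t_stage", "n_stage", "m_stage", "stage"),
) -> pd.DataFrame:
    """Cox fits of survival on clinical covariates plus the risk score.

    ``mode="univariate"``: one single-covariate fit per variable.
    ``mode="multivariate"``: one joint fit on all usable covariates.
    Returns a table of log HR, se, p and 95% CI per covariate.
    Constant covariates are dropped (logged).
    """
    enc = encode_clinical(clinical)[list(covariates)]
    enc["risk_score"] = pd.Series(risk_scores).reindex(clinical.index).astype(float)
    base = clinical[["os_days", "event"]].astype(float)

    usable = []
    for col in enc.columns:
        vals = enc[col].dropna()
        if vals.nunique() < 2:
            logger.info("cox_covariate_analysis: dropped constant covariate %s", col)
            continue
        if any(enc[u].equals(enc[col]) for u in usable):
            logger.info("cox_covariate_analysis: dropped duplicate covariate %s", col)
            continue
        usable.append(col)

    rows = []
    if mode == "univariate":
        for col in usable:
            df = pd.concat([base, enc[col]], axis=1).dropna()
            cph = CoxPHFitter().fit(df, "os_days", "event")
            rows.append(_coxfit_row(cph, col, mode))
    elif mode == "multivariate":
        df = pd.concat([base, enc[usable]], axis=1).dropna()
        cph = CoxPHFitter().fit(df, "os_days", "event")
        rows = [_coxfit_row(cph, col, mode) for col in usable]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows).set_index("covariate")


def _coxfit_row(cph: CoxPHFitter, col: str, mode: str) -> dict:
    s = cph.summary.loc[col]
    return {
        "covariate": col,
        "mode": mode,
        "log_hr": float(s["coef"]),
        "hr": float(s["exp(coef)"]),
        "se": float(s["se(coef)"]),
        "p": float(s["p"]),
        "ci_lo": float(s["coef lower 95%"]),
        "ci_hi": float(s["coef upper 95%"]),
    }


def risk_plot_data(risk_profiles: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Samples ordered by ascending risk with survival annotations."""
    shared = [s for s in risk_profiles.index if s in clinical.index]
    out = risk_profiles.loc[shared, ["risk_score", "group"]].copy()
    out[["os_days", "event"]] = clinical.loc[shared, ["os_days", "event"]]
    out = out.sort_values("risk_score", kind="stable")
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def evaluate_risk_groups(
    risk_profiles: pd.DataFrame,
    clinical: pd.DataFrame,
    horizons_years=(1.0, 3.0, 5.0),
) -> dict:
    """Headline evaluation of a scored set: log-rank p and per-horizon AUCs."""
    shared = [s for s in risk_profiles.index if s in clinical.index]
    prof = risk_profiles.loc[shared]
    times = clinical.loc[shared, "os_days"].to_numpy(dtype=float)
    events = clinical.loc[shared, "event"].to_numpy(dtype=int)
    chi2, p = logrank_test(times, events, prof["group"])
    aucs = {}
    for yrs in horizons_years:
        roc = time_dependent_auc(prof["risk_score"], times, events, yrs * YEAR_DAYS)
        aucs[yrs] = roc.auc
    return {
        "n": len(shared),
        "n_high": int((prof["group"] == "high").sum()),
        "n_low": int((prof["group"] == "low").sum()),
        "logrank_chi2": chi2,
        "logrank_p": p,
        "auc": aucs,
    }
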