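"""Prognostic signature fitting: univariate Cox screen -> LASSO-Cox
selection -> multivariate Cox model -> risk scores and median split.

The univariate screen and the final multivariate model use lifelines
(Efron tie handling).  The L1 path comes from scikit-survival's coxnet;
the penalty strength is chosen by K-fold cross-validated partial-likelihood
deviance (Verweij & van Houwelingen), minimum-deviance rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import logger
from .pairs import PairIndicatorMatrix


@dataclass
class SignatureModel:
    """Fitted pair signature: risk score(s) = sum_i coef_i * indicator_i(s)."""

    pairs: list  # pair IDs "a|b"
    coefficients: np.ndarray
    train_median_cutoff: float
    lasso_lambda: float | None = None
    cv_folds: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValueError("pairs and coefficients must have equal length")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in signature")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite coefficients")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "pairs": list(self.pairs),
            "coefficients": self.coefficients.tolist(),
            "train_median_cutoff": self.train_median_cutoff,
            "lasso_lambda": self.lasso_lambda,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            pairs=d["pairs"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            train_median_cutoff=d["train_median_cutoff"],
            lasso_lambda=d.get("lasso_lambda"),
            cv_folds=d.get("cv_folds"),
            seed=d.get("seed"),
        )


def _surv_frame(pm: PairIndicatorMatrix, clinical: pd.DataFrame, pair_ids):
    shared = [s for s in pm.sample_ids if s in clinical.index]
    if len(shared) < len(pm.sample_ids) or len(shared) < len(clinical):
        logger.info(
            "model: using %d samples shared between pair matrix and clinical table",
            len(shared),
        )
    X = pm.indicators.loc[list(pair_ids), shared].T.astype(float)
    X["os_days"] = clinical.loc[shared, "os_days"].astype(float)
    X["event"] = clinical.loc[shared, "event"].astype(int)
    return X


def univariate_cox_screen(
    pm: PairIndicatorMatrix, clinical: pd.DataFrame, p_max: float = 0.05
) -> tuple[list, pd.DataFrame]:
    """One-covariate Cox PH fit (Efron ties) per pair; Wald-test filter.

    Returns ``(candidate_pair_ids, table)`` where the table has log_hr, se
    and p per scorable pair.  Constant-indicator and non-converging pairs
    are skipped with a log entry.
    """
    df = _surv_frame(pm, clinical, pm.indicators.index)
    if int(df["event"].sum()) < 30:
        raise ValueError(
            f"univariate screen needs >=30 events (got {int(df['event'].sum())})"
        )
    rows, skipped = [], 0
    base = df[["os_days", "event"]]
    for pid in pm.indicators.index:
        x = df[pid]
        if x.nunique() < 2:
            skipped += 1
            continue
        sub = base.copy()
        sub["x"] = x
        try:
            cph = CoxPHFitter().fit(sub, "os_days", "event")
        except (ConvergenceError, ValueError):
            skipped += 1
            continue
        rows.append({
            "pair_id": pid,
            "log_hr": float(cph.params_["x"]),
            "se": float(cph.standard_errors_["x"]),
            "p": float(cph.summary.loc["x", "p"]),
        })
    if skipped:
        logger.info("univariate_cox_screen: skipped %d pairs", skipped)
    table = pd.DataFrame(rows).set_index("pair_id") if rows else pd.DataFrame(
        columns=["log_hr", "se", "p"]
    )
    candidates = table.index[table["p"] < p_max].tolist()
    return candidates, table


def split_train_test(
    sample_ids, clinical: pd.DataFrame, ratio: float = 0.5, seed: int = 0
) -> tuple[list, list]:
    """Random partition stratified by event status; deterministic given seed."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = [s for s in sample_ids if s in clinical.index]
    rng = np.random.default_rng(seed)
    events = clinical.loc[ids, "event"].astype(int)
    n_train = round(ratio * len(ids))
    strata = [
        [s for s in ids if events[s] == 1],
        [s for s in ids if events[s] == 0],
    ]
    if min(len(g) for g in strata) < 2:
        logger.warning("split_train_test: too few events to stratify; plain split")
        shuffled = list(ids)
        rng.shuffle(shuffled)
        return sorted(shuffled[:n_train]), sorted(shuffled[n_train:])
    train: list = []
    test: list = []
    e_train = round(ratio * len(strata[0]))
    quota = [e_train, n_train - e_train]
    for group, q in zip(strata, quota):
        group = list(group)
        rng.shuffle(group)
        q = int(np.clip(q, 0, len(group)))
        train.extend(group[:q])
        test.extend(group[q:])
    return sorted(train), sorted(test)


def _breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                    beta: np.ndarray) -> float:
    """Breslow-approximation Cox log partial likelihood (used only to score
    the cross-validation folds, matching coxnet's internal tie handling)."""
    lp = X @ beta
    order = np.argsort(-time, kind="stable")
    lp, t, e = lp[order], time[order], event[order]
    cum = np.logaddexp.accumulate(lp)  # log sum exp over risk set (times >= t)
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set for this time includes all tied subjects
        d = e[i:j].sum()
        if d > 0:
            ll += lp[i:j][e[i:j] == 1].sum() - d * cum[j - 1]
        i = j
    return float(ll)


def _event_stratified_folds(event: np.ndarray, k: int, rng) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for mask in (event == 1, event == 0):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(i)
    return [np.sort(np.asarray(f)) for f in folds]


def lasso_select(
    pm_train: PairIndicatorMatrix,
    clinical_train: pd.DataFrame,
    candidates=None,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 40,
    alpha_min_ratio: float = 0.01,
    lambda_rule: str = "min",
    alphas=None,
) -> tuple[list, float, pd.DataFrame]:
    """L1-penalised Cox selection with CV-deviance choice of lambda.

    Fits the coxnet path on the training indicators, scores each lambda by
    the Verweij-van Houwelingen cross-validated partial likelihood and picks
    the minimum-deviance lambda (``lambda_rule="min"``, the default) or the
    sparsest lambda within one standard error of it (``"1se"``, more
    resistant to spurious selection on null data).  Refits on all training
    data and returns ``(selected_pair_ids, lambda, cv_table)``.
    """
    pair_ids = list(candidates) if candidates is not None else list(pm_train.indicators.index)
    df = _surv_frame(pm_train, clinical_train, pair_ids)
    X = df[pair_ids].to_numpy(dtype=float)
    time = df["os_days"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    if event.sum() < cv_folds:
        raise ValueError(f"need >= cv_folds={cv_folds} events (got {event.sum()})")
    y = Surv.from_arrays(event.astype(bool), time)

    if alphas is not None:  # explicit penalty grid (degenerate grids allowed)
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
    else:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio
        )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    rng = np.random.default_rng(seed)
    folds = _event_stratified_folds(event, cv_folds, rng)
    contrib = np.zeros((cv_folds, len(alphas)))
    for f, hold in enumerate(folds):
        keep = np.setdiff1d(np.arange(len(time)), hold)
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        fold_fit.fit(X[keep], y[keep])
        B = fold_fit.coef_  # (p, n_fitted); the path may stop early on a fold
        fitted = {round(float(a), 12): i for i, a in enumerate(fold_fit.alphas_)}
        for a in range(len(alphas)):
            col = fitted.get(round(float(alphas[a]), 12), B.shape[1] - 1)
            beta = B[:, col]
            contrib[f, a] = _breslow_loglik(X, time, event, beta) - _breslow_loglik(
                X[keep], time[keep], event[keep], beta
            )
    cvl = contrib.sum(axis=0)
    cvl_se = contrib.std(axis=0, ddof=1) * np.sqrt(cv_folds)
    best = int(np.argmax(cvl))
    if lambda_rule == "1se":
        # alphas are descending: the first index within one SE is the sparsest
        best = int(np.flatnonzero(cvl >= cvl[best] - cvl_se[best])[0])
    elif lambda_rule != "min":
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    lam = float(alphas[best])
    coefs = path.coef_[:, best]
    selected = [pid for pid, c in zip(pair_ids, coefs) if c != 0.0]
    cv_table = pd.DataFrame(
        {"lambda": alphas, "cv_loglik": cvl, "cv_se": cvl_se, "deviance": -2 * cvl}
    )
    if not selected:
        raise RuntimeError(
            "LASSO shrank every coefficient to zero at the CV-optimal lambda; "
            "the cohort is too small or the effects too weak for selection"
        )
    return selected, lam, cv_table


def _drop_collinear(ind: pd.DataFrame) -> pd.DataFrame:
    """Drop indicator columns that duplicate or complement an earlier column."""
    keep, seen = [], set()
    for col in ind.columns:
        v = tuple(ind[col].astype(int))
        comp = tuple(1 - x for x in v)
        if v in seen or comp in seen:
            logger.info("fit_multivariate_cox: dropped collinear pair %s", col)
            continue
        seen.add(v)
        keep.append(col)
    return ind[keep]


def fit_multivariate_cox(
    pm_train: PairIndicatorMatrix,
    selected_pairs,
    clinical_train: pd.DataFrame,
    lasso_lambda: float | None = None,
    cv_folds: int | None = None,
    seed: int | None = None,
) -> SignatureModel:
    """Unpenalised multivariate Cox fit (Efron ties) on the selected pairs.

    The training-median risk score is stored as the model's cutoff.
    """
    df = _surv_frame(pm_train, clinical_train, selected_pairs)
    ind = _drop_collinear(df[list(selected_pairs)])
    fit_df = ind.copy()
    fit_df[["os_days", "event"]] = df[["os_days", "event"]]
    try:
        cph = CoxPHFitter().fit(fit_df, "os_days", "event")
    except ConvergenceError as exc:
        cond = np.linalg.cond(ind.to_numpy(dtype=float))
        raise RuntimeError(
            f"multivariate Cox did not converge (design condition number {cond:.3g})"
        ) from exc
    coefs = cph.params_.reindex(ind.columns).to_numpy()
    scores = ind.to_numpy(dtype=float) @ coefs
    return SignatureModel(
        pairs=list(ind.columns),
        coefficients=coefs,
        train_median_cutoff=float(np.median(scores)),
        lasso_lambda=lasso_lambda,
        cv_folds=cv_folds,
        seed=seed,
    )


def compute_risk_scores(
    model: SignatureModel, pm: PairIndicatorMatrix, cutoff="median"
) -> pd.DataFrame:
    """Risk score and high/low group per sample.

    ``cutoff`` is ``"median"`` (median of the scored set, the paper-style
    per-set convention), ``"train"`` (the model's training-median cutoff),
    or an explicit number.  ``group`` is high iff score > cutoff.
    """
    missing = [p for p in model.pairs if p not in pm.indicators.index]
    if missing:
        raise KeyError(f"pair matrix lacks signature pairs: {missing}")
    ind = pm.indicators.loc[list(model.pairs)].to_numpy(dtype=float)
    scores = model.coefficients @ ind
    if cutoff == "median":
        cut = float(np.median(scores))
    elif cutoff == "train":
        cut = model.train_median_cutoff
    else:
        cut = float(cutoff)
    return pd.DataFrame(
        {
            "risk_score": scores,
            "group": np.where(scores > cut, "high", "low"),
        },
        index=pd.Index(pm.sample_ids, name="sample_id"),
    )


def fit_signature(
    pm: PairIndicatorMatrix,
    clinical: pd.DataFrame,
    train_ids,
    p_max: float = 0.05,
    cv_folds: int = 10,
    seed: int = 0,
    screen_on: str = "all",
    lambda_rule: str = "min",
) -> tuple[SignatureModel, dict]:
    """Screen -> LASSO -> multivariate Cox on the training set.

    ``screen_on`` is ``"all"`` (univariate screen on the full cohort, the
    stated order of the source protocol) or ``"train"``.
    """
    screen_pm = pm if screen_on == "all" else pm.subset_samples(train_ids)
    candidates, uni_table = univariate_cox_screen(screen_pm, clinical, p_max=p_max)
    if not candidates:
        raise RuntimeError("no prognostic pairs passed the univariate screen")
    pm_train = pm.subset_samples([s for s in train_ids if s in clinical.index])
    selected, lam, cv_table = lasso_select(
        pm_train, clinical, candidates=candidates, cv_folds=cv_folds, seed=seed,
        lambda_rule=lambda_rule,
    )
    model = fit_multivariate_cox(
        pm_train, selected, clinical, lasso_lambda=lam, cv_folds=cv_folds, seed=seed
    )
    details = {
        "candidates": candidates,
        "univariate_table": uni_table,
        "cv_table": cv_table,
        "selected": selected,
    }
    return model, details
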