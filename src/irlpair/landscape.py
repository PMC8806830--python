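"""Association of the risk groups with the clinical and immune landscape.

Chi-square band tests of clinical categories against the high/low risk
split, rank-sum comparisons of continuous per-sample quantities (immune
checkpoint marker expression, predicted drug IC50s), Spearman correlation
of the risk score with immune-cell infiltration fractions from multiple
deconvolution methods, and a time-dependent-AUC comparison of the risk
score against individual clinical covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import YEAR_DAYS, encode_clinical, time_dependent_auc
from .io import UNKNOWN, logger


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def chi2_clinical(
    groups: pd.Series,
    clinical: pd.DataFrame,
    features=("t_stage", "n_stage", "m_stage", "stage", "sex"),
) -> pd.DataFrame:
    """Pearson chi-square of risk group vs each categorical feature.

    Unknown levels are excluded.  Features whose contingency table has an
    empty row/column expectation are skipped with a log entry.
    """
    g = pd.Series(groups).reindex(clinical.index)
    rows = []
    for feat in features:
        levels = clinical[feat].astype(str)
        mask = levels != UNKNOWN
        tab = pd.crosstab(g[mask], levels[mask])
        tab = tab.loc[:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            logger.info("chi2_clinical: skipped degenerate feature %s", feat)
            continue
        try:
            res = stats.chi2_contingency(tab.to_numpy(), correction=False)
        except ValueError:
            logger.info("chi2_clinical: skipped feature %s (zero expectation)", feat)
            continue
        rows.append({
            "feature": feat,
            "test": "chi2",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "stars": significance_stars(res.pvalue),
            "direction": "none",
        })
    return pd.DataFrame(rows).set_index("feature")


def rank_test_by_group(values: pd.Series, groups: pd.Series) -> dict:
    """Two-sided Wilcoxon rank-sum between the high and low risk groups.

    Returns a comparison record with the Mann-Whitney U statistic, p-value
    and direction (which group's values run higher).  All-tied inputs give
    p = 1 with direction 'none'.
    """
    v = pd.Series(values).astype(float)
    g = pd.Series(groups).reindex(v.index)
    hi = v[g == "high"].dropna()
    lo = v[g == "low"].dropna()
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need at least 2 samples per risk group")
    if hi.nunique() == 1 and lo.nunique() == 1 and hi.iloc[0] == lo.iloc[0]:
        return {"test": "wilcoxon", "statistic": float(len(hi) * len(lo) / 2),
                "p": 1.0, "direction": "none", "note": "all values tied"}
    method = "exact" if max(len(hi), len(lo)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    if res.pvalue >= 0.05:
        direction = "none"
    else:
        direction = "higher-in-high" if hi.median() > lo.median() else "higher-in-low"
    return {
        "test": "wilcoxon",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "direction": direction,
    }


def compare_by_group(table: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Rank-sum comparison of every column of a per-sample table by risk group.

    Used identically for ICI-marker expression and per-drug IC50 tables;
    adds BH-adjusted q-values and significance stars.
    """
    rows = []
    for col in table.columns:
        rec = rank_test_by_group(table[col], groups)
        rec["feature"] = col
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = stats.false_discovery_control(out["p"], method="bh")
    out["stars"] = [significance_stars(p) for p in out["p"]]
    return out


def marker_expression_by_group(expr_values: pd.DataFrame, marker_ids, groups) -> pd.DataFrame:
    """Risk-group comparison of checkpoint-marker expression (rows = genes)."""
    present = [m for m in marker_ids if m in expr_values.index]
    missing = set(marker_ids) - set(present)
    if missing:
        logger.info("marker_expression_by_group: markers absent: %s", sorted(missing))
    g = pd.Series(groups)
    table = expr_values.loc[present, g.index].T
    return compare_by_group(table, g)


def infiltration_correlation(
    risk_scores: pd.Series, fractions: pd.DataFrame, sep: str = "|"
) -> pd.DataFrame:
    """Spearman correlation of risk score with each (cell type, method) fraction.

    Columns of ``fractions`` are named ``"<cell_type>|<method>"`` (samples as
    rows).  Constant fractions are skipped.  BH adjustment is applied within
    each deconvolution method; the unadjusted p is reported alongside.
    """
    rs = pd.Series(risk_scores)
    shared = rs.index.intersection(fractions.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for col in fractions.columns:
        cell, _, method = col.partition(sep)
        vals = fractions.loc[shared, col].astype(float)
        if vals.nunique() < 2:
            logger.info("infiltration_correlation: skipped constant fraction %s", col)
            continue
        rho, p = stats.spearmanr(rs.loc[shared], vals)
        rows.append({
            "cell_type": cell,
            "method": method or "unknown",
            "rho": float(rho),
            "p": float(p),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for method, idx in out.groupby("method").groups.items():
        out.loc[idx, "q"] = stats.false_discovery_control(out.loc[idx, "p"], method="bh")
    return out


def clinical_roc_compare(
    risk_scores: pd.Series,
    clinical: pd.DataFrame,
    horizon_years: float = 1.0,
    covariates=("age", "sex", "t_stage", "n_stage", "m_stage", "stage"),
) -> pd.DataFrame:
    """Time-dependent AUC of the risk score vs each clinical covariate.

    Each covariate is treated as a univariate marker at the same horizon.
    """
    enc = encode_clinical(clinical)[list(covariates)]
    enc["risk_score"] = pd.Series(risk_scores).reindex(clinical.index)
    horizon = horizon_years * YEAR_DAYS
    rows = []
    for col in enc.columns:
        sub = pd.concat(
            [enc[col], clinical[["os_days", "event"]]], axis=1
        ).dropna()
        roc = time_dependent_auc(
            sub[col], sub["os_days"], sub["event"], horizon
        )
        rows.append({"predictor": col, "auc": roc.auc,
                     "n_cases": roc.n_cases, "n_controls": roc.n_controls})
    return pd.DataFrame(rows).set_index("predictor").sort_values("auc", ascending=False)
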