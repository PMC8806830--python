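"""Immune-related lncRNA screening.

Two stages: (1) flag lncRNAs coexpressed with at least one immune gene
(|Pearson r| above a threshold at a p-value cutoff, computed across tumor
samples); (2) keep those that are differentially expressed between tumor
and normal samples (Wilcoxon rank-sum, BH-adjusted FDR, |log2FC| filter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, FormatError, logger

#: pseudocount (FPKM) stabilising log2 fold changes of zero-expression genes
PSEUDOCOUNT = 1e-3


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlations between two (genes x samples) blocks."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A**2).sum(axis=1))
    sb = np.sqrt((B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A @ B.T) / np.outer(sa, sb)
    return np.clip(r, -1.0, 1.0)


def coexpression_screen(
    expr: ExpressionMatrix,
    immune_ids,
    lnc_ids,
    r_min: float = 0.4,
    p_max: float = 1e-3,
) -> list[str]:
    """Return the lncRNAs correlated with at least one immune gene.

    A lncRNA qualifies if |Pearson r| > ``r_min`` with p < ``p_max`` against
    any immune gene, computed over tumor samples.  Constant-expression genes
    have no defined correlation and are skipped (logged).
    """
    immune_ids, lnc_ids = list(immune_ids), list(lnc_ids)
    if not immune_ids:
        raise FormatError("empty immune gene set")
    if not 0 < r_min < 1:
        raise ValueError("r_min must be in (0, 1)")
    missing = (set(immune_ids) | set(lnc_ids)) - set(expr.gene_ids)
    if missing:
        raise FormatError(f"genes absent from expression matrix: {sorted(missing)[:5]}")
    tumor = expr.values[expr.tumor_ids]
    n = tumor.shape[1]
    if n < 3:
        raise FormatError("need at least 3 tumor samples for correlation")

    L = tumor.loc[lnc_ids].to_numpy(dtype=float)
    M = tumor.loc[immune_ids].to_numpy(dtype=float)
    const_l = L.std(axis=1) == 0
    const_m = M.std(axis=1) == 0
    if const_l.any() or const_m.any():
        logger.info(
            "coexpression_screen: skipped %d constant genes",
            int(const_l.sum() + const_m.sum()),
        )
    r = _pearson_matrix(L, M)
    # exact t-distributed p-value for Pearson r under bivariate normality
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    hit = (np.abs(r) > r_min) & (p < p_max)
    hit[const_l, :] = False
    hit[:, const_m] = False
    return [g for g, h in zip(lnc_ids, hit.any(axis=1)) if h]


def differential_expression(expr: ExpressionMatrix, gene_ids=None) -> pd.DataFrame:
    """Tumor-vs-normal differential expression table.

    Per gene: ``log2fc`` = log2((mean_tumor + eps) / (mean_normal + eps)),
    two-sided Wilcoxon rank-sum p-value, Benjamini-Hochberg ``fdr``, and a
    ``direction`` (up/down in tumor) consistent with the sign of log2fc.
    """
    tumor_ids, normal_ids = expr.tumor_ids, expr.normal_ids
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise FormatError(
            f"differential expression needs >=2 samples per class "
            f"(got {len(tumor_ids)} tumor, {len(normal_ids)} normal)"
        )
    genes = list(gene_ids) if gene_ids is not None else expr.gene_ids
    T = expr.values.loc[genes, tumor_ids].to_numpy(dtype=float)
    N = expr.values.loc[genes, normal_ids].to_numpy(dtype=float)
    log2fc = np.log2((T.mean(axis=1) + PSEUDOCOUNT) / (N.mean(axis=1) + PSEUDOCOUNT))
    res = stats.mannwhitneyu(T, N, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # fully tied rows carry no evidence
    fdr = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=pd.Index(genes, name="gene_id"),
    )


def filter_de(de: pd.DataFrame, fdr_max: float = 0.01, lfc_min: float = 2.0) -> list[str]:
    """Genes with fdr < ``fdr_max`` and |log2fc| > ``lfc_min`` (both directions)."""
    if fdr_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    keep = (de["fdr"] < fdr_max) & (de["log2fc"].abs() > lfc_min)
    return de.index[keep].tolist()


def screen_irlncs(
    expr: ExpressionMatrix,
    immune_ids,
    lnc_ids,
    r_min: float = 0.4,
    p_max: float = 1e-3,
    fdr_max: float = 0.01,
    lfc_min: float = 2.0,
    de_first: bool = False,
):
    """Full screen: coexpression with immune genes, then tumor/normal DE.

    Returns ``(de_irlnc_ids, irlnc_ids, de_table)``.  ``de_first=True``
    swaps the stage order (DE on all lncRNAs, then the coexpression screen);
    the retained set is the same intersection either way, but the FDR
    correction is then applied across all lncRNAs instead of the
    immune-correlated subset.
    """
    if de_first:
        de = differential_expression(expr, lnc_ids)
        de_ids = filter_de(de, fdr_max, lfc_min)
        irlnc = coexpression_screen(expr, immune_ids, lnc_ids, r_min, p_max)
        return sorted(set(de_ids) & set(irlnc)), irlnc, de
    irlnc = coexpression_screen(expr, immune_ids, lnc_ids, r_min, p_max)
    if not irlnc:
        logger.warning("screen_irlncs: no immune-related lncRNAs found")
        return [], [], pd.DataFrame(columns=["log2fc", "p_value", "fdr", "direction"])
    de = differential_expression(expr, irlnc)
    return filter_de(de, fdr_max, lfc_min), irlnc, de
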