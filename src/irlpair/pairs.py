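"""Rank-based pair indicator features (the 0-or-1 matrix).

For every unordered pair (a, b) of DE immune-related lncRNAs, a sample is
scored 1 if expression of a exceeds expression of b in that sample and 0
otherwise (ties score 0).  Because the score only depends on the within-
sample ordering, the features are invariant to any strictly increasing
per-sample transform of expression — no cross-sample normalisation is
needed.  Pairs whose indicator is (nearly) constant across samples carry
no information and are removed by a prevalence validity filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, logger


def pair_id(a: str, b: str) -> str:
    return f"{a}|{b}"


@dataclass
class PairIndicatorMatrix:
    """Binary pairs x samples matrix of relative-ordering indicators.

    ``indicators`` is indexed by "a|b" pair IDs (a < b lexicographically)
    with one 0/1 column per sample; ``pairs`` holds the tuples in row order.
    """

    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.indicators.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        if self.indicators.index.duplicated().any():
            raise ValueError("duplicate pairs")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(pid.split("|", 1)) for pid in self.indicators.index]

    @property
    def sample_ids(self) -> list[str]:
        return self.indicators.columns.tolist()

    @property
    def prevalence(self) -> pd.Series:
        """Fraction of samples scored 1, per pair."""
        return self.indicators.mean(axis=1)

    def subset_samples(self, sample_ids) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.indicators[list(sample_ids)])

    def subset_pairs(self, pair_ids) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.indicators.loc[list(pair_ids)])

    def to_frame(self) -> pd.DataFrame:
        out = self.indicators.copy()
        out.insert(0, "prevalence", self.prevalence)
        out.index.name = "pair_id"
        return out


def build_pair_matrix(
    expr: ExpressionMatrix, gene_ids, samples: str = "tumor"
) -> PairIndicatorMatrix:
    """Score every unordered gene pair in every sample.

    k genes yield k(k-1)/2 rows.  Pair orientation is canonical
    (lexicographically smaller gene first); indicator = 1 iff
    expr[a] > expr[b], strict, so ties score 0.
    """
    genes = sorted(set(gene_ids))
    if len(genes) < 2:
        raise ValueError(f"need at least 2 genes to form pairs (got {len(genes)})")
    missing = set(genes) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)[:5]}")
    cols = expr.tumor_ids if samples == "tumor" else expr.sample_ids
    X = expr.values.loc[genes, cols].to_numpy(dtype=float)
    ai, bi = np.triu_indices(len(genes), k=1)
    ind = (X[ai] > X[bi]).astype(np.int8)
    index = pd.Index([pair_id(genes[i], genes[j]) for i, j in zip(ai, bi)], name="pair_id")
    return PairIndicatorMatrix(pd.DataFrame(ind, index=index, columns=cols))


def filter_valid_pairs(
    pm: PairIndicatorMatrix, low: float = 0.2, high: float = 0.8
) -> PairIndicatorMatrix:
    """Keep pairs whose prevalence lies in [low, high] (inclusive bounds).

    Equivalently both indicator values must each occur in at least a
    ``low`` fraction of samples (for the default symmetric bounds).
    Row order is preserved; the operation is idempotent.
    """
    if not 0 < low < high < 1:
        raise ValueError("need 0 < low < high < 1")
    prev = pm.prevalence
    keep = (prev >= low) & (prev <= high)
    out = PairIndicatorMatrix(pm.indicators.loc[keep])
    if out.indicators.shape[0] == 0:
        logger.warning("filter_valid_pairs: no pairs left after prevalence filter")
    return out


def write_pairs(pm: PairIndicatorMatrix, path) -> None:
    pm.to_frame().to_csv(path, sep="\t")


def read_pairs(path) -> PairIndicatorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairIndicatorMatrix(df.drop(columns=["prevalence"]).astype(np.int8))
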