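"""Readers, writers and validated containers for the pipeline's tabular inputs.

The canonical interchange formats are desk-scale TSV files:

* ``expression.tsv`` — genes x samples FPKM matrix, first column ``gene_id``,
  one column per sample.  Tumor/normal status is carried in the sample
  barcode suffix (``-01`` tumor, ``-11`` normal), mirroring TCGA barcodes.
* ``clinical.tsv`` — one row per tumor sample: ``sample_id``, ``os_days``,
  ``event``, ``t_stage``, ``n_stage``, ``m_stage``, ``stage``, ``age``, ``sex``.
* ``annotation.tsv`` — ``gene_id``, ``symbol``, ``biotype``.
* plain-text gene lists, one symbol/ID per line.
* generic per-sample numeric tables (immune-cell fractions, predicted IC50s).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("irlpair")

TUMOR = "tumor"
NORMAL = "normal"

#: clinical categories treated as missing and excluded from contingency tests
UNKNOWN = "unknown"

_BARCODE_CLASS = {"01": TUMOR, "11": NORMAL}


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


def _sample_class_from_id(sample_id: str) -> str:
    """Infer tumor/normal from a TCGA-like barcode suffix (``-01``/``-11``)."""
    m = re.search(r"-(\d{2})[A-Z]?$", sample_id)
    if m and m.group(1) in _BARCODE_CLASS:
        return _BARCODE_CLASS[m.group(1)]
    raise FormatError(
        f"cannot infer tumor/normal class from sample ID {sample_id!r}; "
        "expected a -01 (tumor) or -11 (normal) barcode suffix"
    )


@dataclass
class ExpressionMatrix:
    """Nonnegative FPKM-like expression, genes x samples, with sample classes.

    ``values`` is indexed by gene ID with one column per sample;
    ``sample_class`` maps every sample ID to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise FormatError("empty expression matrix")
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise FormatError("non-finite expression values")
        if (arr < 0).any():
            raise FormatError("negative expression values")
        if not self.sample_class.index.equals(v.columns):
            self.sample_class = self.sample_class.reindex(v.columns)
        if self.sample_class.isna().any():
            missing = self.sample_class.index[self.sample_class.isna()].tolist()
            raise FormatError(f"samples without tumor/normal class: {missing[:5]}")
        bad = set(self.sample_class.unique()) - {TUMOR, NORMAL}
        if bad:
            raise FormatError(f"unrecognised sample classes: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def tumor_ids(self) -> list[str]:
        return self.sample_class.index[self.sample_class == TUMOR].tolist()

    @property
    def normal_ids(self) -> list[str]:
        return self.sample_class.index[self.sample_class == NORMAL].tolist()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.sample_class.loc[ids])


@dataclass
class GeneAnnotation:
    """gene_id -> (symbol, biotype) with biotype in {lncRNA, protein_coding, other}."""

    table: pd.DataFrame  # index gene_id, columns symbol, biotype

    BIOTYPES = ("lncRNA", "protein_coding", "other")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise FormatError("duplicate gene IDs in annotation")
        unknown = set(t["biotype"].unique()) - set(self.BIOTYPES)
        if unknown:
            # collapse anything unrecognised into 'other' rather than failing:
            # GTFs carry dozens of biotypes and only the lncRNA/coding split matters
            t = t.copy()
            t.loc[t["biotype"].isin(unknown), "biotype"] = "other"
            self.table = t

    def biotype_of(self, gene_id: str) -> str | None:
        if gene_id in self.table.index:
            return str(self.table.at[gene_id, "biotype"])
        return None


CLINICAL_COLUMNS = [
    "sample_id", "os_days", "event",
    "t_stage", "n_stage", "m_stage", "stage", "age", "sex",
]
_CATEGORICAL = ["t_stage", "n_stage", "m_stage", "stage", "sex"]


def read_expression(path, class_from_id=_sample_class_from_id) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV and validate it.

    ``class_from_id`` maps a sample ID to ``"tumor"``/``"normal"``; the default
    parses a TCGA-like ``-01``/``-11`` barcode suffix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    classes = pd.Series({s: class_from_id(s) for s in values.columns})
    return ExpressionMatrix(values, classes.reindex(values.columns))


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    # no float_format: full repr keeps write -> read an exact round trip
    out.to_csv(path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "symbol", "biotype"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation missing column {col!r}")
    return GeneAnnotation(df.set_index("gene_id")[["symbol", "biotype"]])


def annotation_from_gtf(path) -> GeneAnnotation:
    """Build a GeneAnnotation from a standard 9-column GTF (gene features)."""
    import pyranges as pr

    gr = pr.read_gtf(path).df
    genes = gr[gr["Feature"] == "gene"]
    biotype_col = "gene_biotype" if "gene_biotype" in genes.columns else "gene_type"
    table = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "symbol": genes.get("gene_name", genes["gene_id"]),
        "biotype": genes[biotype_col].where(
            genes[biotype_col].isin(["lncRNA", "protein_coding"]), "other"
        ),
    }).drop_duplicates("gene_id")
    return GeneAnnotation(table.set_index("gene_id"))


def classify_genes(expr: ExpressionMatrix, ann: GeneAnnotation) -> tuple[list[str], list[str]]:
    """Partition the expression genes into (lncRNA IDs, protein-coding IDs).

    Genes missing from the annotation or annotated 'other' are dropped;
    the dropped count is logged.
    """
    lnc, coding, dropped = [], [], 0
    for g in expr.gene_ids:
        b = ann.biotype_of(g)
        if b == "lncRNA":
            lnc.append(g)
        elif b == "protein_coding":
            coding.append(g)
        else:
            dropped += 1
    if not lnc and not coding:
        raise FormatError("annotation covers none of the expression genes")
    if dropped:
        logger.info("classify_genes: dropped %d unannotated/other genes", dropped)
    return lnc, coding


def read_clinical(path) -> pd.DataFrame:
    """Read and validate the clinical table (one row per tumor sample).

    Returns a DataFrame indexed by sample_id with ``os_days`` (float, > 0),
    ``event`` (0/1 int), ordinal stage categories (missing -> ``"unknown"``),
    ``age`` (float) and ``sex``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs in clinical table")
    df = df.set_index("sample_id")
    df["os_days"] = df["os_days"].astype(float)
    if (df["os_days"] <= 0).any() or df["os_days"].isna().any():
        bad = df.index[(df["os_days"] <= 0) | df["os_days"].isna()].tolist()
        raise FormatError(f"{path}: non-positive survival time for {bad[:5]}")
    ev = df["event"].astype(float)
    if not ev.isin([0.0, 1.0]).all():
        raise FormatError(f"{path}: event must be 0/1")
    df["event"] = ev.astype(int)
    df["age"] = df["age"].astype(float)
    for col in _CATEGORICAL:
        df[col] = df[col].fillna(UNKNOWN).astype(str).replace({"": UNKNOWN, "nan": UNKNOWN})
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    out = clinical.reset_index()
    if out.columns[0] != "sample_id":
        out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """Read a one-ID-per-line gene list; duplicates are removed (count logged)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln and not ln.startswith("#")]
    unique = list(dict.fromkeys(ids))
    if len(unique) < len(ids):
        logger.info("read_gene_list: removed %d duplicate entries", len(ids) - len(unique))
    if not unique:
        raise FormatError(f"{path}: empty gene list")
    return unique


def read_sample_table(path) -> pd.DataFrame:
    """Read a generic per-sample numeric table (samples as rows).

    Shared reader for immune-cell infiltration fractions and predicted IC50s.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def align_samples(expr: ExpressionMatrix, clinical: pd.DataFrame):
    """Restrict to tumor samples present in both expression and clinical data.

    Returns ``(expr_subset, clinical_subset, n_dropped)`` where ``n_dropped``
    counts tumor samples present in only one of the two inputs.
    """
    tumor = set(expr.tumor_ids)
    clin = set(clinical.index)
    shared = [s for s in expr.sample_ids if s in tumor and s in clin]
    n_dropped = len(tumor ^ clin)
    if not shared:
        raise FormatError("no tumor samples shared between expression and clinical data")
    if n_dropped:
        logger.info("align_samples: dropped %d samples missing from one input", n_dropped)
    return expr.subset_samples(shared), clinical.loc[shared], n_dropped
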