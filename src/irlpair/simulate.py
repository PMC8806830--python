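"""Synthetic LUAD-like cohort generator with known ground truth.

Emulates the statistical structure the IRLP analysis assumes:

* log2-normal FPKM expression (heavy-tailed, nonnegative);
* a subset of lncRNAs coexpressed with immune genes at a configurable
  Pearson correlation (calibrated on the FPKM scale, accounting for
  log-normal attenuation);
* differentially expressed lncRNAs shifted by a configurable log2
  fold change in tumors;
* overall survival drawn from a proportional-hazards model whose log
  hazard is linear in a known set of pair indicators (plus an optional
  T-stage effect), with independent exponential right censoring
  calibrated to a requested censoring fraction.

Everything is driven by one explicit RNG seeded from ``SimConfig.seed``;
identical configs produce bit-identical cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    NORMAL,
    TUMOR,
    logger,
    write_clinical,
    write_expression,
)

#: immune-checkpoint genes always present among the immune genes so that
#: marker-by-risk-group comparisons can be exercised downstream
ICI_MARKERS = ("CD47", "CD274", "LAG3", "CTLA4", "PDCD1")


class InvalidConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


def _lnc_id(i: int) -> str:
    return f"LNC{i + 1:04d}"


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    The survival-relevant fields are the true pair indicators and their
    log-hazard coefficients ``true_betas``; ``baseline_hazard`` is in
    events/day.  ``cor_strength`` is the target Pearson correlation, on
    the FPKM scale, between each coexpressed lncRNA and its immune-gene
    partner.  ``censor_rate`` is the target fraction of censored tumor
    samples.  ``n_clinical`` restricts the clinical table to the first
    ``n_clinical`` tumor samples (``None`` = all), emulating expression
    samples that lack clinical records.
    """

    n_tumor: int = 400
    n_normal: int = 50
    n_lnc: int = 60
    n_immune_genes: int = 40
    n_de_lnc: int = 12
    de_log2fc: float = 3.0
    cor_strength: float = 0.6
    true_pairs: list = field(default_factory=list)
    true_betas: list = field(default_factory=list)
    baseline_hazard: float = math.log(2) / 900.0
    censor_rate: float = 0.3
    seed: int = 0
    # second-order knobs (defaults are the package's study conditions)
    log2_mean_loc: float = 3.0
    log2_mean_scale: float = 1.2
    de_mean_scale: float = 0.5
    log2_sd: float = 0.8
    stage_beta: float = 0.25
    weibull_shape: float = 1.0
    n_clinical: int | None = None
    n_coexpressed: int | None = None  # lncRNAs tied to immune genes; None -> n_de_lnc + 8
    de_directions: list | None = None  # +1/-1 per DE gene; None -> all up

    def validate(self) -> None:
        if self.n_tumor <= 0:
            raise InvalidConfigError("n_tumor must be positive")
        if self.n_normal < 0:
            raise InvalidConfigError("n_normal must be nonnegative")
        if self.n_lnc < 2 or self.n_immune_genes < 1:
            raise InvalidConfigError("need at least 2 lncRNAs and 1 immune gene")
        if not 0 <= self.n_de_lnc <= self.n_lnc:
            raise InvalidConfigError("n_de_lnc must be in [0, n_lnc]")
        if not 0.0 <= self.cor_strength < 1.0:
            raise InvalidConfigError("cor_strength must be in [0, 1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise InvalidConfigError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise InvalidConfigError("baseline_hazard must be positive")
        if len(self.true_pairs) != len(self.true_betas):
            raise InvalidConfigError("true_pairs and true_betas lengths differ")
        if not all(np.isfinite(self.true_betas)):
            raise InvalidConfigError("true_betas must be finite")
        de_ids = set(self.de_lnc_ids)
        for a, b in self.true_pairs:
            if a == b:
                raise InvalidConfigError(f"degenerate pair ({a}, {b})")
            for g in (a, b):
                if g not in de_ids:
                    raise InvalidConfigError(
                        f"true pair gene {g!r} is not a DE lncRNA of this config"
                    )
        if self.de_directions is not None and len(self.de_directions) != self.n_de_lnc:
            raise InvalidConfigError("de_directions must have one sign per DE lncRNA")

    @property
    def lnc_ids(self) -> list[str]:
        return [_lnc_id(i) for i in range(self.n_lnc)]

    @property
    def de_lnc_ids(self) -> list[str]:
        return [_lnc_id(i) for i in range(self.n_de_lnc)]

    @property
    def immune_ids(self) -> list[str]:
        ids = list(ICI_MARKERS[: self.n_immune_genes])
        ids += [f"IMM{i + 1:04d}" for i in range(len(ids), self.n_immune_genes)]
        return ids


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default prognostic cohort: 12 DE lncRNAs forming 6 disjoint
    true pairs with mixed-sign log hazard ratios in [0.45, 0.8]."""
    overrides.setdefault(
        "true_pairs", [(_lnc_id(2 * i), _lnc_id(2 * i + 1)) for i in range(6)]
    )
    overrides.setdefault("true_betas", [0.8, -0.7, 0.6, -0.55, 0.5, -0.45])
    cfg = SimConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def tcga_like_config(seed: int = 0, **overrides) -> SimConfig:
    """A cohort with TCGA-LUAD-like sample counts: 535 tumor / 59 normal
    expression profiles, of which 464 tumors carry clinical records."""
    overrides.setdefault("n_tumor", 535)
    overrides.setdefault("n_normal", 59)
    overrides.setdefault("n_clinical", 464)
    return default_config(seed=seed, **overrides)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Same cohort structure but no survival signal (all betas zero)."""
    cfg = default_config(seed=seed, **overrides)
    cfg.true_betas = [0.0] * len(cfg.true_pairs)
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    de_lnc_ids: list
    signature_pairs: list  # canonical (a < b) orientation
    betas: np.ndarray  # aligned with signature_pairs, canonical orientation
    per_sample_linear_predictor: pd.Series  # pair part only, tumor samples
    stage_linear_predictor: pd.Series
    censor_fraction: float

    def __post_init__(self) -> None:
        if len(self.signature_pairs) != len(self.betas):
            raise InvalidConfigError("betas length must equal signature_pairs length")


@dataclass
class Cohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    annotation: GeneAnnotation
    immune_genes: list
    truth: SyntheticTruth
    config: SimConfig


def _canonical(pair, beta):
    a, b = pair
    return ((a, b), beta) if a < b else ((b, a), -beta)


def _latent_rho(target_r: float, log2_sd: float) -> float:
    """Latent normal correlation giving Pearson ``target_r`` after exponentiation.

    For bivariate log-normal with equal natural-log sd s, the observed
    Pearson correlation is (e^{rho s^2} - 1) / (e^{s^2} - 1); invert it.
    """
    s2 = (log2_sd * math.log(2)) ** 2
    return math.log1p(target_r * math.expm1(s2)) / s2


def _calibrate_censor_rate(times: np.ndarray, target: float) -> float:
    """Exponential-censoring rate giving an expected censored fraction ``target``
    over the realised event times (bisection on the marginal probability)."""
    if target <= 0:
        return 0.0

    def frac(rc):
        return float(np.mean(-np.expm1(-rc * times)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < target:
        hi *= 10
        if hi > 1e12:  # pragma: no cover - pathological time scale
            break
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate expression, clinical data and ground truth for one cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_n = config.n_tumor, config.n_normal
    n_samples = n_t + n_n
    if n_n == 0:
        logger.warning("generate_cohort: cohort has no normal samples; "
                       "differential expression will not be computable")

    lnc_ids = config.lnc_ids
    imm_ids = config.immune_ids
    gene_ids = lnc_ids + imm_ids
    tumor_ids = [f"S{i + 1:04d}-01" for i in range(n_t)]
    normal_ids = [f"S{n_t + i + 1:04d}-11" for i in range(n_n)]
    sample_ids = tumor_ids + normal_ids

    # per-gene baseline log2 means; DE genes share a tighter mean distribution
    # and true-pair partners share the same mean so pair prevalences sit
    # mid-range (informative indicators survive the validity filter)
    mu = rng.normal(config.log2_mean_loc, config.log2_mean_scale, len(gene_ids))
    mu[: config.n_de_lnc] = rng.normal(
        config.log2_mean_loc, config.de_mean_scale, config.n_de_lnc
    )
    pos = {g: i for i, g in enumerate(gene_ids)}
    for a, b in config.true_pairs:
        shared = mu[pos[a]]
        mu[pos[b]] = shared

    # latent log2-scale noise; coexpressed lncRNA/immune partners are
    # bivariate normal with a correlation calibrated for the FPKM scale
    z = rng.standard_normal((len(gene_ids), n_samples))
    n_coex = config.n_coexpressed
    if n_coex is None:
        n_coex = min(config.n_lnc, config.n_de_lnc + 8)
    rho = _latent_rho(config.cor_strength, config.log2_sd) if config.cor_strength else 0.0
    coexpressed = []
    for i in range(n_coex):
        lnc_i = pos[_lnc_id(i)]
        imm_i = pos[imm_ids[i % len(imm_ids)]]
        z[imm_i] = rho * z[lnc_i] + math.sqrt(1 - rho**2) * z[imm_i]
        coexpressed.append((_lnc_id(i), imm_ids[i % len(imm_ids)]))

    log2x = mu[:, None] + config.log2_sd * z

    # tumor-vs-normal differential expression on the DE lncRNAs
    directions = config.de_directions or [1] * config.n_de_lnc
    for i in range(config.n_de_lnc):
        log2x[i, :n_t] += directions[i] * config.de_log2fc

    fpkm = np.round(np.exp2(log2x), 4)
    expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        pd.Series([TUMOR] * n_t + [NORMAL] * n_n, index=sample_ids),
    )

    # canonical pair orientation: indicator is 1 iff expr[a] > expr[b], a < b
    pairs, betas = [], []
    for pair, beta in zip(config.true_pairs, config.true_betas):
        p, b = _canonical(pair, beta)
        pairs.append(p)
        betas.append(b)
    betas = np.asarray(betas, dtype=float)
    tumor_fpkm = fpkm[:, :n_t]
    lp_pairs = np.zeros(n_t)
    for (a, b), beta in zip(pairs, betas):
        ind = (tumor_fpkm[pos[a]] > tumor_fpkm[pos[b]]).astype(float)
        lp_pairs += beta * ind

    # clinical covariates; T stage carries a log-linear hazard effect
    t_stage = rng.choice([1, 2, 3, 4], size=n_t, p=[0.32, 0.38, 0.20, 0.10])
    n_stage = rng.choice([0, 1, 2], size=n_t, p=[0.65, 0.22, 0.13])
    m_stage = rng.choice([0, 1], size=n_t, p=[0.92, 0.08])
    stage = np.where(
        m_stage == 1, 4,
        np.where((n_stage == 2) | (t_stage == 4), 3,
                 np.where((n_stage == 1) | (t_stage == 3), 2, 1)),
    )
    age = np.clip(np.round(rng.normal(65, 10, n_t), 1), 33, 90)
    sex = rng.choice(["male", "female"], size=n_t, p=[0.5, 0.5])

    lp_stage = config.stage_beta * (t_stage - 2.0)
    lp_total = lp_pairs + lp_stage

    # PH survival times: exponential baseline (Weibull when shape != 1)
    e = rng.exponential(1.0, n_t)
    shape = config.weibull_shape
    event_time = (e / np.exp(lp_total)) ** (1.0 / shape) / config.baseline_hazard
    rc = _calibrate_censor_rate(event_time, config.censor_rate)
    censor_time = rng.exponential(1.0 / rc, n_t) if rc > 0 else np.full(n_t, np.inf)
    os_days = np.round(np.maximum(np.minimum(event_time, censor_time), 0.5), 2)
    event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame(
        {
            "os_days": os_days,
            "event": event,
            "t_stage": [f"T{t}" for t in t_stage],
            "n_stage": [f"N{n}" for n in n_stage],
            "m_stage": [f"M{m}" for m in m_stage],
            "stage": [["I", "II", "III", "IV"][s - 1] for s in stage],
            "age": age,
            "sex": sex,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    if config.n_clinical is not None:
        clinical = clinical.iloc[: config.n_clinical]

    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": gene_ids,
                "biotype": ["lncRNA"] * len(lnc_ids) + ["protein_coding"] * len(imm_ids),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )

    truth = SyntheticTruth(
        de_lnc_ids=list(config.de_lnc_ids),
        signature_pairs=pairs,
        betas=betas,
        per_sample_linear_predictor=pd.Series(lp_pairs, index=tumor_ids),
        stage_linear_predictor=pd.Series(lp_stage, index=tumor_ids),
        censor_fraction=float(1 - event.mean()),
    )
    return Cohort(expr, clinical, annotation, imm_ids, truth, config)


def write_fixture(cohort: Cohort, dir_path) -> dict:
    """Write a cohort as the pipeline's canonical TSV/JSON file set.

    Returns a dict of the written paths.  The expression/clinical writers
    round-trip exactly through the :mod:`irlpair.io` readers.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": d / "expression.tsv",
        "clinical": d / "clinical.tsv",
        "annotation": d / "annotation.tsv",
        "immune_genes": d / "immune_genes.txt",
        "truth": d / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    ann = cohort.annotation.table.reset_index()
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    paths["immune_genes"].write_text("\n".join(cohort.immune_genes) + "\n")
    truth = cohort.truth
    payload = {
        "de_lnc_ids": truth.de_lnc_ids,
        "signature_pairs": [list(p) for p in truth.signature_pairs],
        "betas": truth.betas.tolist(),
        "per_sample_linear_predictor": truth.per_sample_linear_predictor.to_dict(),
        "censor_fraction": truth.censor_fraction,
        "n_normal": cohort.config.n_normal,
        "config": {
            k: v for k, v in asdict(cohort.config).items()
            if not isinstance(v, (list, np.ndarray)) or k in ("true_pairs", "true_betas")
        },
    }
    if cohort.config.n_normal == 0:
        payload["flags"] = ["no_normal_samples"]
    paths["truth"].write_text(json.dumps(payload, indent=1, default=str))
    return paths
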