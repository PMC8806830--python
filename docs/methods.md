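# Methods

This note records the statistical model behind `irlpair`, the choices made
where the procedure was genuinely open, and what the synthetic cohort does
and does not establish about real data.

## Pair indicator features

For genes a < b (lexicographic canonical order) and sample s, the feature
is `ind_{a,b}(s) = 1[expr_a(s) > expr_b(s)]`; ties score 0 (strict
inequality). Because the indicator depends only on the within-sample
ordering, any strictly increasing transform of a single sample's
expression vector — rescaling, log transform, quantile normalisation —
leaves the entire feature matrix unchanged. This is the property that
makes pair signatures portable across platforms, and it is enforced by
property tests (random monotone maps) rather than assumed.

The **validity filter** keeps pairs whose indicator prevalence (fraction
of samples scored 1) lies in the closed interval [0.2, 0.8]; equivalently,
both indicator values must each occur in ≥ 20% of samples. A two-sided
rule was chosen over a one-sided "≥ 20% ones" reading because a pair that
is 1 in 95% of samples is as uninformative as one that is 0 in 95%; both
bounds are exposed. Prevalence is computed over all tumor samples before
the train/test split, matching the protocol order (matrix construction
precedes splitting). The filter is idempotent and boundary-inclusive.

## Screening

*Coexpression*: a lncRNA is immune-related if |Pearson r| > 0.4 at
p < 0.001 (t-test, bivariate-normal reference) against at least one
immune gene, computed across tumor samples. The 0.4 / 0.001 defaults are
the convention of the immune-lncRNA signature literature; no published
value exists for this step, so both are configuration parameters.
Constant-expression genes have undefined correlations and are skipped
with a log entry.

*Differential expression*: per gene,
`log2fc = log2((mean_T + ε)/(mean_N + ε))` with pseudocount ε = 0.001
FPKM (stabilises zero-expression genes), a two-sided Wilcoxon rank-sum
p-value (robust to the heavy right tail of FPKM), and Benjamini–Hochberg
FDR. The retention rule is FDR < 0.01 **and |log2fc| > 2** — the absolute
value matters: down-regulated lncRNAs are retained alongside up-regulated
ones. Whether DE should run before or after the immune screen is
ambiguous in the source protocol; the default screens first (FDR is then
computed within the immune-related subset), and `de_first=True` swaps the
order — the retained intersection is the same on strong effects, but the
FDR denominator differs.

## Signature fitting

*Univariate screen*: one Cox fit per pair (lifelines, Efron ties), Wald
p < 0.05. The screen runs on all samples before the split, following the
stated protocol order (`screen_on="train"` is available). Note that under
complete separation the Wald statistic degenerates (Hauck–Donner), so a
"perfectly separating" pair does not necessarily have the smallest Wald p.

*Split*: deterministic, seeded, stratified by event status; with 464
samples at ratio 0.5 the halves are 232/232 and event counts differ by at
most one.

*LASSO-Cox*: the L1 path comes from scikit-survival's coxnet. The penalty
is chosen by K-fold (default 10) cross-validated partial likelihood in
the Verweij–van Houwelingen form, `CV(λ) = Σ_k [ℓ(β̂^(−k); all) −
ℓ(β̂^(−k); all minus fold k)]`, with a Breslow-approximation partial
likelihood for scoring (matching coxnet's internal tie handling). The
default rule is **minimum deviance**; `lambda_rule="1se"` picks the
sparsest λ within one standard error.

A measured limitation of the protocol itself: because the univariate
screen is computed on the full cohort, its selection bias leaks into the
CV folds, and under the min-deviance rule the pipeline keeps 1–2 noise
pairs on *null* cohorts in roughly half of replicates. The 1-SE rule
suppresses this almost entirely but costs real recovery at n = 400. The
default follows the protocol (min deviance); use `lambda_rule="1se"`
when a null-resistant selection matters more than power.

*Final model*: unpenalised multivariate Cox (Efron) on the selected
pairs, after dropping exact-duplicate/complement indicator columns. The
risk score is the linear predictor `Σ β_i ind_i`; the cutoff convention
defaults to the per-set median (the protocol's "median risk score in the
two sets"), with the training-median-applied-everywhere option exposed as
the statistically cleaner alternative.

## Evaluation

Kaplan–Meier and the two-group log-rank test come from lifelines.
The time-dependent AUC is the IPCW cumulative/dynamic (Uno) estimator:
cases have an observed event by the horizon t, controls survive past t,
and each case is weighted by 1/Ĝ(T⁻), the left limit of the reverse-KM
censoring-survival estimate at its event time (deaths precede censorings
at tied times); tied marker values count 1/2. Control weights cancel in
the ratio. This estimator is implemented directly (and verified against
exhaustive weighted pair counting to 1e−10, plus a cross-check against
scikit-survival); it is near-equivalent to, but not identical with, the
smoothed survivalROC variants. Horizons use 365.25 days/year.

Clinical covariates enter Cox models with ordinal stage encodings
(T1–T4 → 1–4, N0–N3 → 0–3, M0/M1 → 0/1, stage I–IV → 1–4), binary sex,
continuous age; "unknown" levels become missing and are dropped per
analysis (and excluded from chi-square contingency tables). Group
comparisons of continuous quantities use the two-sided Mann–Whitney
rank-sum test (exact for ≤ 10 per group) — the groups are independent, so
rank-sum rather than signed-rank is the correct Wilcoxon variant.
Infiltration fractions are correlated with risk by Spearman's rho (robust
to the very different scales of the seven deconvolution methods), with BH
adjustment within each method.

## Nomogram

The multivariate Cox fit (default: T stage + risk score) is rendered as a
points system: `points_j(x) = 100 · β_j (x − ref_j) / max_k |β_k · range_k|`,
where `ref_j` is the covariate's observed minimum-risk value, so every
covariate scores ≥ 0 and the widest-contribution covariate spans exactly
0–100. Predicted survival uses `S(t|x) = S0(t)^exp(β·x)` with the Breslow
baseline at x = 0. Harrell's C is reported **apparent** (no optimism
correction; bootstrap correction is out of scope) and is invariant to
strictly increasing transforms of the linear predictor. Calibration bins
samples by quantiles of predicted survival (default 5 bins; a single bin
reduces to the whole-cohort KM) and compares the bin's mean prediction
with its KM estimate at the horizon; bins whose follow-up does not reach
the horizon are dropped with a log entry. Self-consistency is checked by
simulating n = 2000 subjects exactly from the fitted model (inverse
Breslow cumulative hazard; administrative censoring beyond its support)
and requiring every bin gap ≤ 0.05 at 1/3/5 years.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| n_tumor / n_normal | 400 / 50 | samples (TCGA-like preset: 535 / 59, 464 clinical) |
| n_lnc / n_immune_genes | 60 / 40 | gene panel (immune panel always includes CD47, CD274, LAG3, CTLA4, PDCD1) |
| n_de_lnc, de_log2fc | 12, 3.0 | planted tumor fold change (log2), all up by default |
| cor_strength | 0.6 | FPKM-scale Pearson r to the immune partner |
| true_pairs / true_betas | 6 disjoint pairs, ±[0.45, 0.8] | log hazard per indicator |
| baseline_hazard | ln 2 / 900 d⁻¹ | median survival ≈ 2.5 y at lp = 0 |
| censor_rate | 0.30 | target censored fraction |
| log2_sd | 0.8 | within-gene log2 noise |
| stage_beta | 0.25 | log hazard per T-stage unit |

Expression is log2-normal (per-gene means N(3, 1.2); DE genes draw
tighter means, N(3, 0.5), and true-pair partners share a mean so their
indicator prevalence sits mid-range and survives the validity filter).
Coexpressed lncRNA/immune partners are bivariate normal on the log scale
with latent correlation ρ = log(1 + r(e^{s²}−1))/s² — the analytic
inversion of log-normal attenuation — so the *observed FPKM-scale*
Pearson r converges to `cor_strength`. Survival is exponential (Weibull
shape optional) proportional hazards with linear predictor
Σ β_i ind_i + stage_beta·(T−2), where the indicators are recomputed from
the generated expression; censoring is an independent exponential whose
rate is calibrated by bisection against the realised event times to hit
`censor_rate` in expectation. One `numpy` Generator seeded from
`SimConfig.seed` drives everything; identical configs are bit-identical.
Written values are rounded (FPKM to 4 decimals, days to 2) so the TSV
round trip is exact.

Not emulated: read counts and library-size effects, batch structure,
tumor purity, competing risks, informative censoring, and realistic
lncRNA co-regulation beyond the planted partner links. Passing tests
therefore establish the *correctness and calibration of the machinery*
under the assumed model — not that a signature recovered from TCGA-LUAD
itself would validate.

## Problem sizes and numerics

The test suite uses n = 400 cohorts (50 replicates for recovery, 500
small-cohort replicates for log-rank null uniformity, 1000 null pairs for
screen calibration) and n = 2000 for consistency/calibration checks —
sizes at which the targeted asymptotics are expected to hold while the
suite stays desk-scale. Exact-agreement checks (KM, log-rank, IPCW AUC,
Harrell's C, exact Wilcoxon) run at ≤ 10 subjects against brute-force
enumeration at 1e−10. Ties: pair indicators 0, Cox Efron, concordance
1/2. Seeds are explicit everywhere; hypothesis runs derandomised.
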