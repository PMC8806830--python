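# irlpair

Prognostic modelling of lung adenocarcinoma (LUAD) from **immune-related
lncRNA pairs (IRLPs)** — a rank-based, normalisation-free signature pipeline
with a synthetic cohort generator for end-to-end testing.

Bulk RNA-seq expression units (FPKM, batch, platform) are hard to compare
across cohorts, but the *within-sample ordering* of two genes is not. This
package builds survival signatures from pair indicators

```
ind_{a,b}(s) = 1  if expr_a(s) > expr_b(s),  else 0
```

over immune-related lncRNAs, so a patient can be scored from a single
profile with no cross-sample normalisation. It is aimed at computational
biologists building or stress-testing pair-based prognostic signatures.

## Pipeline

1. **Immune-related lncRNA screen** — lncRNAs with |Pearson r| > 0.4
   (p < 0.001) against ≥ 1 immune gene, across tumor samples.
2. **Differential expression** — Wilcoxon rank-sum tumor vs normal,
   BH FDR < 0.01 and |log2FC| > 2 (both directions).
3. **0-or-1 pair matrix** — every unordered DE-lncRNA pair scored per
   sample as above (ties score 0); a **validity filter** keeps pairs whose
   indicator prevalence lies in [0.2, 0.8] (near-constant pairs carry no
   risk information).
4. **Signature** — univariate Cox screen (Wald p < 0.05), event-stratified
   5:5 train/test split, cross-validated LASSO-Cox selection, and an
   unpenalised multivariate Cox fit. Risk score
   `r(s) = Σ_i β_i · ind_i(s)`; the median splits high/low risk groups.
5. **Evaluation** — Kaplan–Meier + log-rank, IPCW (cumulative/dynamic)
   time-dependent AUC at 1/3/5 years, and uni-/multivariate Cox
   independence against clinical covariates.
6. **Landscape association** — chi-square band analysis, rank-sum tests of
   checkpoint markers (CD47, CD274, LAG3, CTLA4, PDCD1) and predicted drug
   IC50s by risk group, Spearman correlation of risk with immune-cell
   infiltration fractions.
7. **Nomogram** — T stage + risk score Cox model rendered on a 0–100 point
   scale, with Harrell's C and quantile-binned calibration curves.

The `irlpair.simulate` module generates LUAD-like cohorts — log-normal
FPKM, calibrated lncRNA–immune-gene coexpression, planted fold changes,
and exponential proportional-hazards survival driven by a known set of
pair indicators — so every stage is testable against ground truth without
any download.

## Worked example

Run the numbered drivers (each writes tables under `results/`):

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_screen_irlncs.py
python analysis/03_build_pairs.py
python analysis/04_fit_signature.py --seed 2
python analysis/05_evaluate_signature.py
python analysis/06_landscape.py
python analysis/07_nomogram.py
```

Steps 02–04 report the funnel on the simulated cohort — 60 lncRNAs → 20
immune-related → 12 differentially expressed → 66 candidate pairs → 45
valid pairs → 26 prognostic pairs → a 15-pair fitted signature containing
all six planted pairs. Step 05 then prints, for this seed:

```
[train] n=232 (116 high / 116 low): log-rank p = 1.96e-16; AUC 1/3/5 yr = 0.767 / 0.873 / 0.880
[train] independent predictors (multivariate p<0.05): ['t_stage', 'risk_score']
[test] n=232 (116 high / 116 low): log-rank p = 7.59e-08; AUC 1/3/5 yr = 0.698 / 0.677 / 0.771
[test] independent predictors (multivariate p<0.05): ['risk_score']
```

i.e. the high-risk group dies significantly earlier in both halves, the
score discriminates 1-year survival well above chance in the held-out set
(AUC 0.698), and the risk score remains an independent predictor next to
stage covariates. Step 07 reports the nomogram:

```
C-index (apparent): 0.6913
1-year calibration: max |predicted - observed| = 0.054 over 4 bins
```

so of two comparable patients, the one ranked riskier dies first about 69%
of the time, and predicted survival tracks the observed Kaplan–Meier
estimate to within ~5 percentage points per calibration bin.

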