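# Methods

`adloe` re-implements, as a tested pipeline over synthetic cohorts, a
procedure for discovering genetic risk factors shared between
Alzheimer's disease (AD) and late-onset epilepsy (LOE) in EHR-linked
biobank data: phecode phenotyping, an offset-corrected multi-task
elastic net with stability resampling, a shared genetic risk score
(GRS), bidirectional survival association with competing risk of death,
and gene-set enrichment.  This note records the models, the parameter
choices that matter, and the places where the design was genuinely open.

## Phenotyping

ICD-10 encounters are grouped into phecodes (a multimap: one code may
yield several phecodes).  LOE cases need at least one encounter with a
seizure/epilepsy phecode (345, 345.1, 345.11, 345.12, 345.3), the first
such encounter strictly after age 60, and at least one encounter of any
kind before 60 ("strictly after 60" resolves ties at exactly 60.0 to
non-case).  AD cases need one encounter with phecode 290.11.  Controls
must be free of the trait phecodes *and* of their exclude ranges
(290-290.99 for AD, covering e.g. vascular dementia 290.16; 345-345.99
for LOE); everyone else is "excluded" — neither case nor control.  The
"at least one encounter before age 60" clause is read as *any*
encounter.  The built-in phecode map covers exactly the codes this
pipeline emits; a full PheWAS-catalog CSV can be substituted.

Cohort filters: the full analytical sample requires complete
demographics, at least two encounters after 60, and last-visit age in
[60, 90] (ages at 90+ are recorded as 90, a de-identification cap the
simulator reproduces by clamping).  The modeling sample additionally
requires controls to have last-visit age >= 70 and >= 5 years of
records; cases are exempt, and patients with "excluded" status for
either trait are dropped so both task labels are binary.

Summary tables report n (%) for categorical variables (Pearson
chi-square) and mean (SD) for continuous ones (Wilcoxon rank-sum).
Percentages are rounded to two significant figures, the printed
precision of the worked examples the tests pin (571/7,351 -> 7.8%;
44/376 -> 12%; 23/376 -> 6.1%).

## Offset-corrected multi-task elastic net

Let `y_it` be the case indicator of person `i` for task `t` (AD, LOE).
A covariate-only logistic regression per task (age at last visit, sex,
ancestry PCs) gives a linear predictor `eta_it`; the working residual is

    r_it = y_it - expit(eta_it),

i.e. the outcome with the covariate-explained probability subtracted —
the literal "subtract the predicted values" linearization, with Gaussian
loss and no IRLS reweighting.  (A one-step IRLS pseudo-response is
available via `working_response(..., mode="irls")` but is not the
default; for rare outcomes its unweighted use inflates noise.)  The SNP
stage then solves, over the standardized dosage matrix X (train-split
mean 0 / variance 1),

    min_W  (1/2n)||R - 1 b' - X W||_F^2
           + alpha * rho * sum_j ||W_j.||_2
           + (alpha(1-rho)/2) ||W||_F^2,

a row-sparse (l2,1 + ridge) multi-task elastic net: every SNP is
selected jointly for both tasks or not at all.  The solver is cyclic
block coordinate descent with the closed-form block soft-threshold
update; intercepts are unpenalized (with centered X they equal the
residual column means).  Convergence: max coefficient change per sweep
< 1e-6, max 10,000 sweeps; coordinate order is cyclic for determinism.
The fit carries a KKT certificate (`kkt_gap`), and the test suite checks
objective equality (<= 1e-8) against an independent minimizer of the
identical objective on random instances.  `alpha_max = max_j
||X_j'Rc/n||_2 / rho` gives the top of the penalty path (all rows
exactly zero at or above it).  The Gram-form kernel is numba-compiled
when numba is importable, with an identical pure-Python fallback.

### Hyperparameter selection

Grids: alpha log-spaced from `alpha_max` downward (20 points over 3
decades by default), rho in {0.1, 0.3, 0.5, 0.7, 0.9}; K-fold CV (5
folds) on the mean out-of-fold Gaussian log-likelihood of the residual
predictions, warm-started down each alpha path.  The selected point is
chosen by the **one-standard-error rule** (the most sparsity-inducing
grid point — largest alpha*rho — whose CV score is within one SE of the
best), not by the plain CV maximizer.  Rationale: in this regime (p of
a few hundred, n of a few thousand) the CV curve is flat once the
signal is captured, and the plain maximizer drifts into near-dense fits
that select dozens of null SNPs at stability frequencies above the
retention bar, destroying the selection stage; the 1-SE rule is the
standard remedy for flat CV curves and restores sparse, stable
selection while leaving out-of-fold fit statistically unchanged.
`rule="min"` remains available.

## Stability resampling and the shared-risk rule

The whole selection pipeline — stratified 80/20 train/test split,
offset refit, grid search, multi-task fit — is repeated `n_iter` times
(1,000 by default; the canned studies use 100) with seeds spawned from
one base seed.  "Selected" means the SNP's coefficient row is exactly
nonzero (the block penalty makes per-task selection coincide; no
epsilon).  SNPs selected in >= 25% of iterations are retained; the
shared-risk set is the subset whose across-iteration mean coefficients
(zeros included) are nonzero and same-sign for both tasks.  Magnitudes
are reported per task as |mean standardized coefficient|, ranked by the
larger of the two, ties broken by SNP id.  Bootstrap resampling is
available behind `resample="bootstrap"`.

Two caveats the recovery study quantifies.  First, the same-direction
rule has no magnitude floor, so a genuinely causal *single-task* SNP
that stays retained enters the shared set whenever its (tiny,
dataset-frozen) cross-task mean happens to share sign — roughly a coin
flip per SNP that resampling cannot average away.  The recovery study
therefore reports two error rates: the primary false-discovery
proportion against SNPs with *no causal role*, and a strict variant
counting these direction-misassigned single-task SNPs as false.
Second, with 10 single-task causal SNPs in the reference architecture
the strict variant is ~1/3 in expectation by construction; the primary
FDP is what the null run and the 25% bar actually control.

Per-iteration test AUPRCs (precision-recall step integral; constant
scores score the prevalence) are recorded for the multi-task fit and
for single-task elastic nets tuned on the same folds, and compared by
paired Wilcoxon signed-rank (exact null up to 25 informative pairs,
normal approximation with continuity correction beyond; zero
differences dropped, Pratt variant behind a flag).

## Shared genetic risk score

Weights come from one joint logistic regression of the combined
"AD or LOE" outcome (union of case flags; patients excluded for either
trait are dropped) on all shared SNP dosages in the training split,
with the covariate-only linear predictor as a fixed offset; scores are
`sum_j beta_j * dosage_ij`, standardized by training-split mean and SD.
Evaluation on the held-out split: logistic OR per SD adjusted for age
at last visit, sex and the first five PCs, with explained variance
`100 * (dev_reduced - dev_full) / dev_reduced` from the nested
covariate-only model.  The non-APOE variant drops SNPs inside
chr19:44,891,220-44,919,349 (GRCh38, inclusive; the dense
TOMM40-APOE-APOC1 LD block) and refits on the training split.
Quasi-separation anywhere in these logistic fits falls back to a tiny
ridge penalty (1e-6) and is flagged.

## APOE-ε4, PRS, QC, PCs

The ε4 haplotype is rs429358-C with rs7412-C; with unphased genotypes
the count is min(#C at rs429358, #C at rs7412), which resolves the
ambiguous double heterozygote as ε2/ε4 (count 1) — the standard
assumption given ε1's rarity.  Dosage input is rounded first.  PRS is
the weighted dosage sum over an external weight file (never hardcoded),
with the same APOE window exclusion.  QC drops SNPs with >5%
missingness, empirical MAF <1%, imputation r^2 <0.90 (when annotated),
monomorphic or strand-ambiguous (A/T, C/G) alleles, then samples with
>5% missingness; the operation is idempotent and reports per-filter
counts.  PCs are SVD scores of mean-imputed, standardized dosages
(optional every-k-th-SNP thinning); reference-panel ancestry assignment
is out of scope, so PCs describe structure within the cohort itself.
Candidate SNPs: GWAS p < 5e-8 AND (>= 1 positional/eQTL/chromatin
mapping flag OR CADD >= 12.37), pooled over source traits.

## Survival association

Records use age as the timescale with delayed entry at the first visit
(all eligibility rules are age-based; `timescale="study"` is the
alternative).  Entry = max(age at first visit, 60); exit = first of
outcome onset, death, last visit.  Exposure is classified at baseline,
and patients whose outcome precedes the exposure onset are excluded
(count reported) — time-varying exposure is deliberately not modeled.
Cause-specific Cox fits use lifelines (Efron ties), with one ridge-
penalized retry (L2 = 0.1, flagged) if Newton steps stall on sparse
covariates.  The Fine-Gray subdistribution model is fitted as a
weighted Cox on counting-process-expanded data: subjects who die stay
in later risk sets with IPCW weights G(t)/G(t_death), where G is the
Kaplan-Meier estimate of the censoring distribution; when there are
more distinct event times than `max_breaks` (60) the weight-update grid
is coarsened to event-time quantiles, keeping the expansion near-linear
in cohort size (exact below the cap, and exactly equal to Cox when no
competing events exist).  The lifelines time-varying fitter provides no
sandwich variance, so reported Fine-Gray CIs use the weighted
partial-likelihood information; under the administrative censoring of
the calibration studies all weights are 1 and this is the standard
variance.

## Synthetic cohort generator

Dosages: two haplotypes per person; within each LD block a latent
Gaussian AR(1) process (coefficient `ld_rho`, default 0.3, block size
10) is thresholded at the MAF quantile (MAF ~ U(0.05, 0.5)); blocks are
independent.  Phenotypes are logistic on the liability

    logit(q_t) + sum_j beta_jt (d_j - mean) + a_t (age_last - mean)
               + s_t (sex - mean),

matching the downstream logit link (not a probit liability threshold).
Base prevalences default to the modeling-cohort rates (AD 3.77%, LOE
6.59%).  The reference architecture has 10 shared same-sign causal
SNPs, 5 AD-only and 5 LOE-only, spread across blocks; the first shared
SNP is APOE-ε4-like (AD log-odds 1.05 ~ OR 2.85, LOE 0.18 ~ OR 1.20,
placed at chr19:44,905,243 inside the exclusion window; its dosage
doubles as the ε4 count — the two-SNP haplotype encoder is tested on
constructed genotype pairs instead).  Remaining shared effects are
drawn from log-odds 0.45-0.65 (AD) and 0.40-0.60 (LOE) with
alternating sign pairs.  These ranges are a power design: on the
probability-residual scale a shared SNP's joint detection z-score at
the training size (n = 3,200) is about beta * 10.6, so betas >= 0.45
put every shared SNP at z >= ~4.8, above the expected maximum of ~190
null SNPs (~3.3); weaker choices put the tail of the shared effects
below the null noise floor, where no selection procedure can recover
them.  Per-task effects (0.3-0.5) deliberately straddle that boundary.

Mortality is exponential from age 60 (rate 0.01/yr, multiplied by 3 for
cases) and truncates the record; onsets are kept 0.5 years before death
so the coded history stays consistent.  Observed labels flip with
`misclassification_rate` (default 0); truth (roles, betas, liabilities,
true labels) is emitted alongside.  Encounters: every case gets its
trait ICD-10 code at the onset age (LOE onsets are forced after 60.5
and case first visits before 60, so the closed loop with phenotyping is
exact at zero noise), controls get only benign/comorbidity codes,
everyone gets >= 2 encounters after 60 unless flagged sparse, record
spans default to 2-25 years.

What the generator does *not* emulate: temporal ordering between the
two diseases (onsets are independent given the labels, so after the
outcome-before-exposure exclusion the synthetic cross-trait hazard
ratios sit at or below 1 — the positive bidirectional association seen
in real EHR cohorts needs a direct cross-condition dependence the
liability model deliberately omits, since truth must remain
reconstructable as intercept + genetics + demographics); realistic
haplotype panels, imputation error, pedigree or ancestry admixture;
diagnosis-code noise beyond symmetric label flips.  Survival-fitter
correctness is therefore established by the two-group exponential
calibration studies (known HR = 2; shared outcome/death hazards for the
Fine-Gray attenuation pattern), not by the synthetic cohort's HRs.

## Canned study sizes

The recovery and null studies run at n = 4,000 individuals, p = 200
SNPs, 100 stability iterations, grids of 12 alphas over 2.5 decades x
rho {0.1, 0.5, 0.9} with 5-fold CV — a grid coarse enough to keep the
resampling loop quick and dense enough for stable selection; Cox
calibration uses 10 replicates of n = 2,000, the Fine-Gray studies
n = 2,000/400.  The pipeline demo (`adloe run`) defaults to 50
iterations.

## Known limitations

- The shared-direction rule is sign-only; magnitude-blind admission of
  retained single-task SNPs is inherent (quantified above).
- Fine-Gray CIs lack a sandwich correction under genuinely random
  censoring (weights < 1); point estimates are unaffected.
- The 1-SE selection rule trades a little sensitivity for specificity;
  with effects near the null noise floor it abstains rather than
  over-selects.
- PCs are cohort-internal; no reference-panel ancestry inference.
- The enrichment background defaults to the union of collection genes,
  not a curated protein-coding universe.
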