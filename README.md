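# adloe — shared genetic risk of Alzheimer's disease and late-onset epilepsy

Alzheimer's disease (AD) and late-onset epilepsy (LOE, first seizures
after age 60) show a bidirectional epidemiological relationship, but
with no LOE GWAS available, standard cross-trait methods (LDSC,
conjFDR) cannot probe their shared genetics.  `adloe` implements an
EHR-based alternative end to end: phenotype both conditions from ICD-10
encounter streams with phecodes, regress out demographics and ancestry,
jointly model both outcomes over candidate SNP dosages with a
**multi-task elastic net**, stabilize the selection by resampling, and
carry the resulting shared-risk SNPs into a genetic risk score,
competing-risks survival models, and gene-set enrichment.  It is aimed
at statistical geneticists and EHR methodologists who want a tested,
fully synthetic-data-backed reference implementation of this workflow.

## The model

For tasks t ∈ {AD, LOE}, a covariate-only logistic fit gives offsets
η and working residuals r = y − expit(η).  SNP effects solve

    min_W  (1/2n)‖R − 1bᵀ − XW‖²_F + αρ Σⱼ ‖W_{j·}‖₂ + (α(1−ρ)/2)‖W‖²_F

by block coordinate descent — the row-wise ℓ2,1 penalty selects each
SNP jointly for both tasks.  (α, ρ) come from K-fold CV with the
one-standard-error rule; the whole pipeline is repeated over seeded
80/20 resamples, SNPs selected in ≥ 25% of iterations are retained, and
those whose mean coefficients share sign across tasks form the
**shared-risk set**.  A shared GRS (Σⱼ β̂ⱼ·dosageᵢⱼ, standardized on the
training split) is evaluated on held-out data; survival association
uses Cox and Fine–Gray (IPCW-weighted risk sets) on the age timescale;
enrichment is hypergeometric with Benjamini–Hochberg adjustment and a
more-than-one-overlapping-gene rule.  Details: `docs/methods.md`.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic
cohort with known ground truth (4,000 individuals × 200 SNPs; 10 truly
shared causal SNPs including an APOE-ε4-like locus, 5 per-task causal
each):

```bash
python analysis/01_simulate_cohort.py      --seed 1 --out results
python analysis/02_phenotype_cohort.py     --out results
python analysis/03_survival_associations.py --seed 1 --out results
python analysis/04_multitask_stability.py  --seed 1 --out results
python analysis/05_shared_grs.py           --seed 1 --out results
python analysis/06_enrichment.py           --seed 1 --out results
```

Selected output from that run:

```
phenotyped 4000 patients; label agreement with simulated truth 100.0%
recovery (n=4000, p=200, 100 iterations): shared set of 10 SNPs;
  sensitivity 0.90, FDP vs non-causal 0.00 (strict 0.10)
ad: AUPRC multi-task 0.122 vs single-task 0.117 (paired Wilcoxon p=1.6e-11)
Cox calibration: mean HR 2.033 for truth 2.0; Fine-Gray 1.15 < Cox 2.68
  under a shared death hazard (attenuation as expected)
GRS ~ ad_or_loe: OR per SD 3.57 (2.78, 4.58), p=2.3e-23, explains 19.53%
10 shared SNPs -> 10 genes; 1 of 21 sets significant
  SHARED_ARCHITECTURE: overlap 9/14, adjusted p=2.1e-07
```

Reading this: phenotyping reproduces the generator's labels exactly at
zero noise; the stability pipeline recovers 9 of the 10 truly shared
SNPs with no non-causal false discoveries (one retained single-task SNP
slips into the shared set through the sign rule — the "strict 0.10");
the multi-task fit predicts both outcomes slightly but systematically
better than per-trait elastic nets; the survival fitters recover a
known hazard ratio and show the expected Fine–Gray attenuation under
competing mortality; and the GRS built from the recovered set is
strongly associated with the combined phenotype in held-out data, with
the enrichment test flagging exactly the gene set built around the true
shared architecture.

`adloe run --out pipeline_out --seed 1` drives the same stages from a
single config with a hashed artifact manifest; `adloe simulate` writes
a cohort (TSV + dosage VCF) for use elsewhere.

## Layout

```
src/adloe/        library: simulate, phenotyping, genetics, multitask,
                  stability, grs, survival, enrichment, metrics,
                  pipeline, io, cli
analysis/         numbered study drivers (thin wrappers over the library)
tests/            pytest suite incl. end-to-end acceptance checks
scripts/          acceptance.py
docs/methods.md   models, parameter choices, limitations
```

Real patient-level inputs (encounter tables, dosage VCFs, phecode maps,
GMT collections) plug into the same functions; the synthetic generator
exists so every stage is testable without restricted data.
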