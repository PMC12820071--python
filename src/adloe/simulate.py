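"""Synthetic EHR + genotype cohorts with known ground truth.

The generator emulates the data architecture of an EHR-linked biobank
study of Alzheimer's disease (AD) and late-onset epilepsy (LOE): two
correlated binary phenotypes driven by shared same-direction SNP effects
plus task-specific effects, a strong APOE-ε4-like locus (large AD effect,
small same-sign LOE effect), demographic confounders, LD-block-structured
dosages, competing mortality, and ICD-10-coded encounters with optional
label misclassification.  Every downstream stage of the pipeline can be
tested against the emitted :class:`TruthRecord` without any external
data.

Dosages follow a Gaussian-copula AR(1) scheme: within each LD block a
latent AR(1) Gaussian process is thresholded at the MAF quantile on each
of two haplotypes, so adjacent-SNP correlation decays like ``ld_rho**|i-j|``
on the latent scale; blocks are independent.  Phenotypes are logistic on
the linear liability (logit link), matching the downstream offset model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genetics import APOE_REGION, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "default_config",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_encounters",
]

TASKS = ("ad", "loe")


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Causal architecture is given as lists of ``(snp_index, beta_ad,
    beta_loe)`` log-odds triples; shared entries must have same-sign
    betas.  ``apoe_like_index`` marks one shared entry as the APOE-ε4-like
    locus — its annotation is placed inside the chr19 exclusion window
    and its dosage doubles as the ε4 allele count.
    """

    n_individuals: int = 4000
    n_snps: int = 200
    ld_block_size: int = 10
    ld_rho: float = 0.3
    maf_range: tuple = (0.05, 0.5)
    shared_causal: list = field(default_factory=list)   # (idx, b_ad, b_loe)
    ad_only_causal: list = field(default_factory=list)  # (idx, b_ad)
    loe_only_causal: list = field(default_factory=list)  # (idx, b_loe)
    apoe_like_index: int | None = None
    demographic_effects: dict = field(default_factory=lambda: {
        # per-task log-odds: per year of age at last visit, and for female sex
        "ad": {"age": 0.08, "sex": 0.20},
        "loe": {"age": 0.03, "sex": -0.10},
    })
    base_prevalence: dict = field(default_factory=lambda: {
        # modeling-cohort prevalences: 376/9,986 AD and 658/9,986 LOE
        "ad": 0.0377, "loe": 0.0659,
    })
    mortality_rate: float = 0.01          # per-year hazard from age 60
    case_mortality_multiplier: float = 3.0
    misclassification_rate: float = 0.0
    record_span_range: tuple = (2.0, 25.0)
    first_visit_age_range: tuple = (48.0, 59.5)
    encounter_rate: float = 0.8           # extra encounters per record-year
    sparse_record_fraction: float = 0.0   # patients flagged for filter tests
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
        for trait, q in self.base_prevalence.items():
            if not (0.0 < q < 1.0):
                raise ValueError(f"base_prevalence[{trait!r}] outside (0,1)")
        if not (0.0 <= self.misclassification_rate < 0.5):
            raise ValueError("misclassification_rate must lie in [0, 0.5)")
        idx_lists = [
            [i for i, *_ in self.shared_causal],
            [i for i, *_ in self.ad_only_causal],
            [i for i, *_ in self.loe_only_causal],
        ]
        flat = [i for lst in idx_lists for i in lst]
        if len(flat) != len(set(flat)):
            raise ValueError("causal index lists must be pairwise disjoint")
        if any(i < 0 or i >= self.n_snps for i in flat):
            raise ValueError("causal indices must lie below n_snps")
        for _, b_ad, b_loe in self.shared_causal:
            if b_ad * b_loe <= 0:
                raise ValueError("shared causal betas must share sign")
        if self.apoe_like_index is not None and \
                self.apoe_like_index not in idx_lists[0]:
            raise ValueError("apoe_like_index must be a shared causal SNP")

    def beta_matrix(self) -> np.ndarray:
        """True log-odds effects as an n_snps x 2 (AD, LOE) matrix."""
        B = np.zeros((self.n_snps, 2))
        for i, b_ad, b_loe in self.shared_causal:
            B[i] = (b_ad, b_loe)
        for i, b_ad in self.ad_only_causal:
            B[i, 0] = b_ad
        for i, b_loe in self.loe_only_causal:
            B[i, 1] = b_loe
        return B

    def snp_roles(self) -> np.ndarray:
        roles = np.array(["null"] * self.n_snps, dtype=object)
        for i, *_ in self.shared_causal:
            roles[i] = "shared"
        for i, *_ in self.ad_only_causal:
            roles[i] = "ad_only"
        for i, *_ in self.loe_only_causal:
            roles[i] = "loe_only"
        return roles


def default_config(seed: int = 0, n_snps: int = 200, n_shared: int = 10,
                   n_ad_only: int = 5, n_loe_only: int = 5,
                   **overrides) -> SimulationConfig:
    """Reference architecture: 10 shared, 5 AD-only and 5 LOE-only causal
    SNPs among 200 (counts scale down for smaller panels), with the first
    shared SNP as the APOE-ε4-like locus (AD log-odds 1.05 ≈ the ε4 odds
    ratio of 2.85; LOE log-odds 0.18 ≈ OR 1.2).  Remaining shared effects
    alternate sign pairs with standardized magnitudes above 0.1.  Causal
    SNPs are spread evenly across the panel (hence across LD blocks)."""
    rng = np.random.default_rng(seed + 7_654_321)
    total = n_shared + n_ad_only + n_loe_only
    if total == 0:
        cfg = dict(n_snps=n_snps, seed=seed, apoe_like_index=None)
        cfg.update(overrides)
        return SimulationConfig(**cfg)
    idx = np.unique(np.linspace(2, n_snps - 3, total).astype(int))
    if len(idx) < total:
        raise ValueError(f"n_snps={n_snps} too small for {total} causal SNPs")
    shared_idx = list(idx[0::2][:n_shared])
    rest = [i for i in idx if i not in shared_idx]
    ad_idx = rest[:n_ad_only]
    loe_idx = rest[n_ad_only:n_ad_only + n_loe_only]
    shared = []
    for k, i in enumerate(shared_idx):
        if k == 0:
            shared.append((int(i), 1.05, 0.18))
            continue
        sign = 1.0 if k % 2 else -1.0
        shared.append((int(i), sign * rng.uniform(0.45, 0.65),
                       sign * rng.uniform(0.40, 0.60)))
    ad_only = [(int(i), rng.uniform(0.3, 0.5) * (1 if k % 2 else -1))
               for k, i in enumerate(ad_idx)]
    loe_only = [(int(i), rng.uniform(0.3, 0.5) * (1 if k % 2 else -1))
                for k, i in enumerate(loe_idx)]
    cfg = dict(n_snps=n_snps, shared_causal=shared, ad_only_causal=ad_only,
               loe_only_causal=loe_only, apoe_like_index=int(shared_idx[0]),
               seed=seed)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the simulated cohort."""

    snp_table: pd.DataFrame    # snp_id, role, beta_ad, beta_loe
    liabilities: pd.DataFrame  # patient_id, liability_ad/loe, true labels

    def shared_snps(self) -> list:
        return list(self.snp_table.loc[self.snp_table["role"] == "shared",
                                       "snp_id"])


# ---------------------------------------------------------------------------
# genotypes


def _simulate_haplotype_block(rng, n, block_maf, ld_rho):
    """One haplotype for one LD block via the latent AR(1) copula."""
    m = len(block_maf)
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    c = np.sqrt(1.0 - ld_rho ** 2)
    for j in range(1, m):
        z[:, j] = ld_rho * z[:, j - 1] + c * rng.standard_normal(n)
    return (z < norm.ppf(block_maf)).astype(np.int8)


def simulate_genotypes(config: SimulationConfig):
    """Draw the dosage matrix and its SNP annotation.

    Two independent haplotypes per individual; within each block the
    latent Gaussian is AR(1) with coefficient ``ld_rho``.  Annotation
    carries simulated GWAS p-values (smaller for causal SNPs), CADD
    scores, mapping flags and source-trait labels so the candidate
    filter downstream is exercised; the APOE-like SNP sits inside the
    chr19 exclusion window.  A trailing block shorter than
    ``ld_block_size`` is simply truncated.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_snps
    maf = rng.uniform(*config.maf_range, size=p)
    dosages = np.empty((n, p), dtype=np.int8)
    for start in range(0, p, config.ld_block_size):
        stop = min(start + config.ld_block_size, p)
        h1 = _simulate_haplotype_block(rng, n, maf[start:stop], config.ld_rho)
        h2 = _simulate_haplotype_block(rng, n, maf[start:stop], config.ld_rho)
        dosages[:, start:stop] = h1 + h2

    snp_ids = [f"snp{j:04d}" for j in range(p)]
    roles = config.snp_roles()
    causal = roles != "null"
    gwas_p = 10.0 ** -rng.uniform(8.1, 12.0, size=p)
    gwas_p[causal] = 10.0 ** -rng.uniform(12.0, 30.0, size=causal.sum())
    cadd = rng.uniform(0.0, 35.0, size=p)
    cadd[causal] = rng.uniform(12.37, 35.0, size=causal.sum())
    mapped_pos = rng.random(p) < 0.8
    mapped_eqtl = rng.random(p) < 0.3
    mapped_chrom = rng.random(p) < 0.2
    source = np.where(roles == "loe_only", "epilepsy", "AD")
    # one epilepsy-GWAS shared SNP, echoing the 7-of-8 AD-origin split
    shared_pos = np.flatnonzero(roles == "shared")
    if shared_pos.size > 1:
        source[shared_pos[-1]] = "epilepsy"

    chroms = np.empty(p, dtype=object)
    pos = np.empty(p, dtype=np.int64)
    autosomes = [str(c) for c in range(1, 23) if c != 19]
    for j in range(p):
        block = j // config.ld_block_size
        chroms[j] = autosomes[block % len(autosomes)]
        pos[j] = 1_000_000 + 10_000 * j
    if config.apoe_like_index is not None:
        chroms[config.apoe_like_index] = APOE_REGION[0]
        pos[config.apoe_like_index] = 44_905_243

    alleles = np.array(["A", "C", "G", "T"])
    eff = rng.choice(alleles, size=p)
    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    other = np.array([rng.choice([a for a in alleles
                                  if a not in (e, complement[e])])
                      for e in eff])
    annotation = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": chroms,
        "pos": pos,
        "effect_allele": eff,
        "other_allele": other,
        "maf": maf,
        "gwas_p": gwas_p,
        "cadd": cadd,
        "mapped_positional": mapped_pos,
        "mapped_eqtl": mapped_eqtl,
        "mapped_chromatin": mapped_chrom,
        "source_trait": source,
        "mapped_genes": [f"GENE{j // 2:03d}" for j in range(p)],
    })
    samples = [f"pt{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snp_ids,
                          dosages=dosages.astype(float)), annotation


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(genotypes: GenotypeMatrix,
                        config: SimulationConfig):
    """Draw demographics, case labels, mortality and comorbidities.

    Liability per task t: logit(base_prevalence_t)
    + sum_j beta_jt (dosage_j - 2 maf_j) + age_t (planned last-visit age
    - 75) + sex_t * female.  Case indicators are Bernoulli(expit
    (liability)); observed labels flip with ``misclassification_rate``.
    Death is exponential from age 60 with a case multiplier and truncates
    the record; case onset ages are kept before death so the coded
    history remains consistent.
    """
    if genotypes.n_snps != config.n_snps:
        raise ValueError("genotype matrix does not match config n_snps")
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_samples
    D = genotypes.dosages
    B = config.beta_matrix()
    centered = D - D.mean(axis=0)

    sex = rng.integers(0, 2, size=n)  # 1 = female
    first = rng.uniform(*config.first_visit_age_range, size=n)
    span = rng.uniform(*config.record_span_range, size=n)
    planned_last = np.minimum(first + span, 90.0)  # de-identification cap

    liab = np.empty((n, 2))
    true_case = np.empty((n, 2), dtype=int)
    for t, trait in enumerate(TASKS):
        eff = config.demographic_effects[trait]
        liab[:, t] = (np.log(config.base_prevalence[trait]
                             / (1 - config.base_prevalence[trait]))
                      + centered @ B[:, t]
                      + eff["age"] * (planned_last - planned_last.mean())
                      + eff["sex"] * (sex - sex.mean()))
        true_case[:, t] = rng.random(n) < 1.0 / (1.0 + np.exp(-liab[:, t]))

    observed = true_case.copy()
    if config.misclassification_rate > 0:
        flips = rng.random((n, 2)) < config.misclassification_rate
        observed = np.where(flips, 1 - observed, observed)

    any_case = observed.any(axis=1)
    last = planned_last.copy()
    # guarantee room for a post-60 onset in coded histories
    last[observed[:, 0] == 1] = np.maximum(last[observed[:, 0] == 1], 62.0)
    last[observed[:, 1] == 1] = np.maximum(last[observed[:, 1] == 1], 62.0)

    onset = np.full((n, 2), np.nan)
    for t in range(2):
        cases = np.flatnonzero(observed[:, t])
        lo = np.maximum(60.5, first[cases] + 0.5)
        onset[cases, t] = rng.uniform(lo, last[cases])

    haz = config.mortality_rate * np.where(
        any_case, config.case_mortality_multiplier, 1.0)
    death_age = 60.0 + rng.exponential(1.0 / haz, size=n)
    max_onset = np.nanmax(np.where(np.isnan(onset), -np.inf, onset), axis=1)
    death_age = np.where(any_case,
                         np.maximum(death_age, max_onset + 0.5), death_age)
    deceased = death_age < last
    last = np.where(deceased, death_age, last)

    def comorbid(base_logit, case_shift):
        lp = base_logit + case_shift * any_case
        return (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)

    cohort = pd.DataFrame({
        "patient_id": genotypes.samples,
        "sex": sex,
        "age_first_visit": first,
        "age_last_visit": last,
        "record_length": last - first,
        "deceased": deceased.astype(int),
        "death_age": np.where(deceased, death_age, np.nan),
        "ad_case": observed[:, 0],
        "loe_case": observed[:, 1],
        "ad_onset_age": onset[:, 0],
        "loe_onset_age": onset[:, 1],
        "hypertension": comorbid(-0.62, 1.4),
        "diabetes": comorbid(-2.1, 0.8),
        "stroke": comorbid(-5.1, 2.1),
        "hyperlipidemia": comorbid(-0.85, 1.1),
        "sparse_record": (rng.random(n)
                          < config.sparse_record_fraction).astype(int),
    })
    truth = TruthRecord(
        snp_table=pd.DataFrame({
            "snp_id": genotypes.snps,
            "role": config.snp_roles(),
            "beta_ad": B[:, 0],
            "beta_loe": B[:, 1],
        }),
        liabilities=pd.DataFrame({
            "patient_id": genotypes.samples,
            "liability_ad": liab[:, 0],
            "liability_loe": liab[:, 1],
            "true_ad": true_case[:, 0],
            "true_loe": true_case[:, 1],
            "planned_age_last_visit": planned_last,
        }),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# encounters


_BENIGN_ICD = ["Z00.00", "Z01.419", "I25.10", "M54.5", "K21.9"]
_TRAIT_ICD = {"ad": "G30.9", "loe": "G40.909"}
_COMORBIDITY_ICD = {"hypertension": "I10", "diabetes": "E11.9",
                    "stroke": "I63.9", "hyperlipidemia": "E78.5"}


def simulate_encounters(cohort: pd.DataFrame, icd_map,
                        config: SimulationConfig) -> pd.DataFrame:
    """Emit an ICD-10-coded encounter stream consistent with the cohort.

    Every case receives an encounter bearing its trait code at the onset
    age (LOE codes therefore first appear after 60 by construction);
    controls receive only benign / comorbidity codes; every patient gets
    at least two encounters after 60 unless flagged ``sparse_record``.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    required = {"ad": "290.11", "loe": "345.1"}
    mapped = set(icd_map.entries["phecode"])
    for trait, phecode in required.items():
        if phecode not in mapped:
            raise ValueError(f"phecode map lacks required phecode {phecode} "
                             f"({trait})")
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        first, last = rec.age_first_visit, rec.age_last_visit
        rows.append((pid, first, rng.choice(_BENIGN_ICD)))
        if last > 60.0:
            lo = max(60.0, first) + 1e-3
            n_after = 1 if rec.sparse_record else max(
                2, rng.poisson(config.encounter_rate * (last - lo)))
            for age in rng.uniform(lo, last, size=n_after):
                rows.append((pid, age, rng.choice(_BENIGN_ICD)))
        for trait in TASKS:
            if getattr(rec, f"{trait}_case"):
                rows.append((pid, getattr(rec, f"{trait}_onset_age"),
                             _TRAIT_ICD[trait]))
        for flag, icd in _COMORBIDITY_ICD.items():
            if getattr(rec, flag):
                rows.append((pid, rng.uniform(first, last), icd))
    out = pd.DataFrame(rows, columns=["patient_id", "age", "icd10"])
    return out.sort_values(["patient_id", "age"]).reset_index(drop=True)
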