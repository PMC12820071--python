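"""Dosage-level genetics: QC, ancestry PCs, APOE-ε4 coding, PRS, candidates.

Works on imputed dosage matrices (samples x SNPs, values in [0, 2]) with a
per-SNP annotation table carrying position (GRCh38), alleles, MAF, GWAS
p-value, CADD score, functional-mapping flags and source trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "APOE_REGION",
    "GenotypeMatrix",
    "qc_filter",
    "compute_pcs",
    "apoe_e4_count",
    "compute_prs",
    "select_candidates",
]

#: Dense-LD window around TOMM40/APOE/APOC1 excluded from non-APOE scores:
#: chr19, GRCh38, 1-based inclusive endpoints.
APOE_REGION = ("19", 44_891_220, 44_919_349)

#: Annotation columns expected by the candidate filter.
MAPPING_FLAGS = ["mapped_positional", "mapped_eqtl", "mapped_chromatin"]


@dataclass
class GenotypeMatrix:
    """Sample-by-SNP dosage matrix; NaN marks missing dosages."""

    samples: list
    snps: list
    dosages: np.ndarray  # n x p float, entries in [0, 2] or NaN

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.samples) or p != len(self.snps):
            raise ValueError("dosage matrix dimensions do not match ids")
        valid = np.isnan(self.dosages) | (
            (self.dosages >= 0.0) & (self.dosages <= 2.0))
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def empirical_maf(self) -> np.ndarray:
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = (np.arange(self.n_samples) if sample_idx is None
                      else np.asarray(sample_idx))
        snp_idx = (np.arange(self.n_snps) if snp_idx is None
                   else np.asarray(snp_idx))
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            snps=[self.snps[j] for j in snp_idx],
            dosages=self.dosages[np.ix_(sample_idx, snp_idx)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples,
                            columns=self.snps)


# ---------------------------------------------------------------------------
# QC


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def qc_filter(genotypes: GenotypeMatrix, annotation: pd.DataFrame,
              max_snp_missing: float = 0.05, min_maf: float = 0.01,
              min_imputation_r2: float = 0.90,
              max_sample_missing: float = 0.05):
    """Apply standard dosage-level QC and report per-filter drop counts.

    Drops SNPs with missingness > 5%, empirical MAF < 1%, imputation r²
    < 0.90 (when the annotation carries an ``imputation_r2`` column),
    monomorphic dosages, or strand-ambiguous (A/T, C/G) allele pairs;
    then drops samples with > 5% missingness.  Returns
    (filtered GenotypeMatrix, filtered annotation, drop-count dict).
    The operation is idempotent.
    """
    annotation = annotation.set_index("snp_id").loc[genotypes.snps].reset_index() \
        if "snp_id" in annotation.columns and list(annotation["snp_id"]) != list(genotypes.snps) \
        else annotation.reset_index(drop=True)
    if len(annotation) != genotypes.n_snps:
        raise ValueError("annotation must cover every SNP in the matrix")

    miss = genotypes.snp_missingness()
    maf = genotypes.empirical_maf()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns
        mono = np.nanstd(genotypes.dosages, axis=0) == 0.0
    drop_missing = miss > max_snp_missing
    drop_maf = maf < min_maf
    pairs = list(zip(annotation["effect_allele"].str.upper(),
                     annotation["other_allele"].str.upper()))
    drop_ambig = np.array([p in _AMBIGUOUS for p in pairs])
    if "imputation_r2" in annotation.columns:
        r2 = annotation["imputation_r2"].to_numpy(dtype=float)
        drop_r2 = np.where(np.isnan(r2), False, r2 < min_imputation_r2)
    else:
        drop_r2 = np.zeros(genotypes.n_snps, dtype=bool)
    drop_any = drop_missing | drop_maf | drop_ambig | drop_r2 | mono
    counts = {
        "snp_missingness": int(drop_missing.sum()),
        "snp_maf": int(drop_maf.sum()),
        "snp_ambiguous": int(drop_ambig.sum()),
        "snp_imputation_r2": int(np.asarray(drop_r2).sum()),
        "snp_monomorphic": int(mono.sum()),
        "snp_total": int(drop_any.sum()),
    }
    keep_snps = np.flatnonzero(~drop_any)
    if keep_snps.size == 0:
        raise ValueError(f"all SNPs removed by QC: {counts}")
    out = genotypes.subset(snp_idx=keep_snps)
    ann_out = annotation.iloc[keep_snps].reset_index(drop=True)

    smiss = out.sample_missingness()
    keep_samples = np.flatnonzero(smiss <= max_sample_missing)
    counts["samples"] = int(out.n_samples - keep_samples.size)
    out = out.subset(sample_idx=keep_samples)
    return out, ann_out, counts


# ---------------------------------------------------------------------------
# ancestry PCs


def compute_pcs(genotypes: GenotypeMatrix, k: int,
                thin_step: int = 1) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the (mean-imputed, standardized) dosages.

    A light LD-naive thinning (keep every ``thin_step``-th SNP) is
    available for dense panels.  Returns (score table with columns
    PC1..PCk indexed by sample, explained-variance fractions).
    """
    D = genotypes.dosages[:, ::thin_step].copy()
    n, p = D.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n, p)={min(n, p)}")
    col_mean = np.nanmean(D, axis=0)
    nan_idx = np.where(np.isnan(D))
    D[nan_idx] = np.take(col_mean, nan_idx[1])
    D -= col_mean
    sd = D.std(axis=0)
    sd[sd == 0.0] = 1.0
    D /= sd
    if k == 0:
        return (pd.DataFrame(index=genotypes.samples), np.array([]))
    U, S, _ = np.linalg.svd(D, full_matrices=False)
    scores = U[:, :k] * S[:k]
    evr = (S ** 2) / (S ** 2).sum()
    table = pd.DataFrame(scores, index=genotypes.samples,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return table, evr[:k]


# ---------------------------------------------------------------------------
# APOE-ε4 count


def _c_allele_count(genotype, snp: str) -> int:
    """Number of C alleles from an allele pair ('C/T') or a dosage.

    For dosage input the stored dosage is assumed to count the C allele
    at both sites (rs429358-C and rs7412-C are the ε4-defining alleles).
    """
    if isinstance(genotype, str):
        alleles = genotype.replace("|", "/").upper().split("/")
        if len(alleles) != 2 or any(a not in "ACGT" for a in alleles):
            raise ValueError(f"malformed {snp} genotype: {genotype!r}")
        return sum(a == "C" for a in alleles)
    d = float(genotype)
    if not 0.0 <= d <= 2.0:
        raise ValueError(f"{snp} dosage outside [0, 2]: {d}")
    return int(round(d))


def apoe_e4_count(rs429358, rs7412) -> int:
    """Number of APOE ε4 haplotypes (0, 1 or 2).

    The ε4 haplotype carries rs429358-C together with rs7412-C.  With
    unphased genotypes every configuration resolves uniquely except the
    double heterozygote (ε2/ε4 vs the ε1/ε3 resolution); following common
    practice the ε2/ε4 reading is used, since ε1 is vanishingly rare.
    Under that convention the count is min(#C at rs429358, #C at rs7412).
    """
    c1 = _c_allele_count(rs429358, "rs429358")
    c2 = _c_allele_count(rs7412, "rs7412")
    return min(c1, c2)


# ---------------------------------------------------------------------------
# polygenic risk score


def _in_apoe_region(annotation: pd.DataFrame) -> np.ndarray:
    chrom = annotation["chrom"].astype(str).str.removeprefix("chr")
    pos = annotation["pos"].to_numpy(dtype=float)
    c, lo, hi = APOE_REGION
    return (chrom == c).to_numpy() & (pos >= lo) & (pos <= hi)


def compute_prs(genotypes: GenotypeMatrix, weights: pd.DataFrame,
                exclude_apoe: bool = False,
                annotation: pd.DataFrame | None = None) -> pd.Series:
    """Weighted risk-allele dosage sum, PRS_i = sum_j beta_j * dosage_ij.

    ``weights`` needs columns ``snp_id`` and ``beta``.  Weight SNPs absent
    from the matrix are skipped with a warning.  With ``exclude_apoe``
    every SNP inside the chr19 TOMM40--APOE--APOC1 window is removed
    before summation (requires ``annotation`` with chrom/pos).
    """
    w = weights.set_index("snp_id")["beta"]
    if exclude_apoe:
        if annotation is None:
            raise ValueError("annotation required for APOE-region exclusion")
        inside = _in_apoe_region(annotation)
        excluded = set(np.asarray(annotation["snp_id"])[inside])
        w = w[~w.index.isin(excluded)]
    present = [s for s in w.index if s in set(genotypes.snps)]
    n_missing = len(w) - len(present)
    if n_missing:
        warnings.warn(f"{n_missing} weight SNPs absent from matrix; skipped")
    if not present:
        raise ValueError("no weighted SNPs present in the genotype matrix")
    idx = [genotypes.snps.index(s) for s in present]
    D = genotypes.dosages[:, idx]
    D = np.where(np.isnan(D), np.nanmean(D, axis=0), D)
    scores = D @ w.loc[present].to_numpy()
    return pd.Series(scores, index=genotypes.samples, name="prs")


# ---------------------------------------------------------------------------
# candidate SNP selection


def select_candidates(annotation: pd.DataFrame,
                      p_threshold: float = 5e-8,
                      cadd_threshold: float = 12.37) -> list:
    """Genome-wide significant, putatively deleterious SNPs.

    Keeps SNPs with GWAS p < 5e-8 AND (at least one positional / eQTL /
    chromatin mapping flag OR CADD >= 12.37), pooled over source traits.
    """
    sig = annotation["gwas_p"].to_numpy(dtype=float) < p_threshold
    flags = annotation[MAPPING_FLAGS].to_numpy(dtype=bool).any(axis=1)
    cadd = annotation["cadd"].to_numpy(dtype=float) >= cadd_threshold
    keep = sig & (flags | cadd)
    return list(annotation.loc[keep, "snp_id"])
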