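"""Readers/writers for the pipeline's text artifacts.

Tables travel as tab-separated text with a header; dosage matrices as
VCF with a ``DS`` (dosage) FORMAT field plus a sidecar SNP-annotation
TSV.  Reading VCF goes through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix

__all__ = ["write_table", "read_table", "write_vcf_dosages",
           "read_vcf_dosages"]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf_dosages(genotypes: GenotypeMatrix,
                      annotation: pd.DataFrame, path) -> Path:
    """Write dosages as a VCF 4.2 file with one DS value per sample."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann = annotation.set_index("snp_id")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        for chrom in dict.fromkeys(annotation["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in genotypes.samples) + "\n")
        for j, snp in enumerate(genotypes.snps):
            row = ann.loc[snp]
            ds = ["." if np.isnan(d) else f"{d:g}"
                  for d in genotypes.dosages[:, j]]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t"
                     f"PASS\t.\tDS\t" + "\t".join(ds) + "\n")
    return path


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Read a DS-format VCF back into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, cols = [], []
    for variant in vcf:
        snps.append(variant.ID)
        ds = np.asarray(variant.format("DS"), dtype=float).reshape(-1)
        cols.append(ds)
    dosages = np.column_stack(cols) if cols else \
        np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)
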