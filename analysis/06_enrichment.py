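"""Hypergeometric gene-set enrichment of the shared-risk genes: map the
shared SNPs to genes through their annotation lists and test against a
gene-set collection (a GMT file, or the built-in demo collection over
the simulated gene universe).

    python analysis/06_enrichment.py [--seed 1] [--out results]
       [--gmt sets.gmt]
"""

import argparse
from pathlib import Path

from adloe import enrichment as enr
from adloe import io
from adloe.pipeline import demo_gene_sets, derive_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--gmt", type=Path, default=None)
    args = ap.parse_args()
    data = args.out / "data"

    shared = io.read_table(args.out / "shared_risk.tsv")
    ann = io.read_table(data / "snp_annotation.tsv")
    genes = enr.map_shared_snps_to_genes(shared, ann)
    if args.gmt:
        collection = enr.read_gmt(args.gmt)
    else:
        truth = io.read_table(data / "truth_snps.tsv")
        collection = demo_gene_sets(ann, truth,
                                    seed=derive_seed(args.seed,
                                                     "enrichment"))
    table = enr.hypergeom_test(genes, collection)
    io.write_table(table, args.out / "enrichment.tsv")
    sig = table[table["significant"]]
    print(f"{len(shared)} shared SNPs -> {len(genes)} genes; "
          f"{len(sig)} of {len(table)} sets significant "
          "(BH-adjusted p <= 0.05 and overlap > 1)")
    for r in sig.itertuples():
        print(f"  {r.set_name}: overlap {r.overlap}/{r.set_size}, "
              f"adjusted p={r.p_adjusted:.2g}")


if __name__ == "__main__":
    main()
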