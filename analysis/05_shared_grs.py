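"""Build and evaluate the shared AD-LOE genetic risk score from the
shared-risk SNPs found in step 04: joint logistic weights on the
training split, standardized scoring, held-out associations with the
combined and single-trait phenotypes, and the non-APOE sensitivity
variant.

    python analysis/05_shared_grs.py [--seed 1] [--out results]
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from adloe import grs, io
from adloe.io import read_vcf_dosages
from adloe.pipeline import derive_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out / "data"

    shared = io.read_table(args.out / "shared_risk.tsv")
    if shared.empty:
        raise SystemExit("no shared-risk SNPs found in step 04")
    cohort = io.read_table(data / "cohort_simulated.tsv")
    genos = read_vcf_dosages(data / "genotypes.vcf")
    ann = io.read_table(data / "snp_annotation.tsv")
    dose = genos.to_frame().loc[cohort["patient_id"]]
    covs = np.column_stack([cohort["age_last_visit"], cohort["sex"]])
    y = ((cohort["ad_case"] == 1)
         | (cohort["loe_case"] == 1)).to_numpy(float)

    rng = np.random.default_rng(derive_seed(args.seed, "grs_split"))
    test = rng.random(len(cohort)) < 0.2
    model = grs.fit_grs_weights(dose[~test], list(shared["snp_id"]),
                                y[~test], covs[~test])
    io.write_table(model.weights.rename_axis("snp_id").reset_index(),
                   args.out / "grs_weights.tsv")
    scores = grs.score(dose, model)

    phenos = {"ad_or_loe": y,
              "ad_only": cohort["ad_case"].to_numpy(float),
              "loe_only": cohort["loe_case"].to_numpy(float)}
    rows = []
    for name, yv in phenos.items():
        a = grs.test_association(scores[test], yv[test], covs[test],
                                 label=name)
        rows.append(asdict(a))
        print(f"GRS ~ {name}: OR per SD {a.odds_ratio:.2f} "
              f"({a.ci_lower:.2f}, {a.ci_upper:.2f}), p={a.p_value:.2g}, "
              f"explains {a.explained_variance_pct:.2f}% "
              f"(test n={a.n})")
    try:
        variant = grs.build_non_apoe_variant(model, ann, dose[~test],
                                             y[~test], covs[~test])
        s2 = grs.score(dose, variant)
        a = grs.test_association(s2[test], y[test], covs[test],
                                 label="ad_or_loe_non_apoe")
        rows.append(asdict(a))
        print(f"non-APOE GRS ({len(variant.snps)} SNPs) ~ AD or LOE: "
              f"OR per SD {a.odds_ratio:.2f} ({a.ci_lower:.2f}, "
              f"{a.ci_upper:.2f})")
    except ValueError as err:
        print(f"non-APOE variant skipped: {err}")
    io.write_table(pd.DataFrame(rows), args.out / "grs_associations.tsv")


if __name__ == "__main__":
    main()
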