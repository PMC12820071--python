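"""Generator contracts: LD structure, seeded determinism, phenotype model
calibration, label noise, and encounter-stream consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from adloe import phenotyping, simulate
from adloe.simulate import SimulationConfig, default_config


def _config(**kw):
    base = dict(n_individuals=200, n_snps=20, ld_block_size=5, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_bad_maf_range(self):
        with pytest.raises(ValueError, match="maf_range"):
            _config(maf_range=(0.3, 0.1))

    def test_rejects_bad_prevalence(self):
        with pytest.raises(ValueError, match="base_prevalence"):
            _config(base_prevalence={"ad": 1.2, "loe": 0.05})

    def test_rejects_opposite_sign_shared_betas(self):
        with pytest.raises(ValueError, match="same-sign|share sign"):
            _config(shared_causal=[(1, 0.5, -0.5)])

    def test_rejects_overlapping_causal_lists(self):
        with pytest.raises(ValueError, match="disjoint"):
            _config(shared_causal=[(1, 0.5, 0.5)], ad_only_causal=[(1, 0.3)])

    def test_rejects_out_of_range_index(self):
        with pytest.raises(ValueError, match="below n_snps"):
            _config(ad_only_causal=[(99, 0.3)])


class TestGenotypes:
    def test_seed_determinism_bitwise(self):
        cfg = _config()
        g1, a1 = simulate.simulate_genotypes(cfg)
        g2, a2 = simulate.simulate_genotypes(cfg)
        assert np.array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(a1, a2)

    def test_dosages_in_range(self):
        g, _ = simulate.simulate_genotypes(_config())
        assert g.dosages.min() >= 0 and g.dosages.max() <= 2

    def test_zero_ld_gives_independent_snps(self):
        cfg = _config(n_individuals=5000, ld_rho=0.0, n_snps=10,
                      ld_block_size=5, maf_range=(0.2, 0.5))
        g, _ = simulate.simulate_genotypes(cfg)
        corr = np.corrcoef(g.dosages.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_ar1_decay_matches_bruteforce_oracle(self):
        """Adjacent-SNP dosage correlation matches an independent
        brute-force simulation of the same latent AR(1) copula."""
        rho, maf = 0.8, 0.3
        # oracle: direct large-n two-haplotype simulation, written
        # independently of the generator internals
        rng = np.random.default_rng(99)
        n_oracle = 200_000
        thr = norm.ppf(maf)
        dos = np.zeros((n_oracle, 2))
        for _ in range(2):  # two haplotypes
            z1 = rng.standard_normal(n_oracle)
            z2 = rho * z1 + np.sqrt(1 - rho ** 2) * \
                rng.standard_normal(n_oracle)
            dos[:, 0] += z1 < thr
            dos[:, 1] += z2 < thr
        target = np.corrcoef(dos.T)[0, 1]

        cfg = _config(n_individuals=10_000, n_snps=10, ld_block_size=10,
                      ld_rho=rho, maf_range=(maf, maf + 1e-9))
        g, _ = simulate.simulate_genotypes(cfg)
        got = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1]
        assert got == pytest.approx(target, abs=0.05)

    def test_trailing_block_truncated_not_error(self):
        g, _ = simulate.simulate_genotypes(_config(n_snps=23,
                                                   ld_block_size=5))
        assert g.n_snps == 23

    def test_annotation_flags_causal_snps_significant(self):
        cfg = default_config(seed=5, n_individuals=100, n_snps=60,
                             n_shared=4, n_ad_only=2, n_loe_only=2)
        _, ann = simulate.simulate_genotypes(cfg)
        causal = cfg.snp_roles() != "null"
        assert (ann.loc[causal, "gwas_p"] < 5e-8).all()
        assert (ann.loc[causal, "cadd"] >= 12.37).all()


class TestPhenotypes:
    def test_null_model_prevalence_calibrated(self):
        cfg = _config(n_individuals=20_000, n_snps=10,
                      base_prevalence={"ad": 0.05, "loe": 0.05},
                      demographic_effects={"ad": {"age": 0, "sex": 0},
                                           "loe": {"age": 0, "sex": 0}})
        g, _ = simulate.simulate_genotypes(cfg)
        cohort, _ = simulate.simulate_phenotypes(g, cfg)
        # 99% binomial interval around 0.05 at n=20,000 is ~(0.046, 0.054)
        assert 0.045 <= cohort["ad_case"].mean() <= 0.055
        assert 0.045 <= cohort["loe_case"].mean() <= 0.055

    def test_larger_beta_widens_dosage_gap_both_tasks(self):
        gaps = {}
        for beta in (0.4, 0.8):
            cfg = _config(n_individuals=20_000, n_snps=10,
                          shared_causal=[(2, beta, beta)],
                          base_prevalence={"ad": 0.1, "loe": 0.1})
            g, _ = simulate.simulate_genotypes(cfg)
            cohort, _ = simulate.simulate_phenotypes(g, cfg)
            d = g.dosages[:, 2]
            gaps[beta] = tuple(
                d[cohort[f"{t}_case"] == 1].mean()
                - d[cohort[f"{t}_case"] == 0].mean()
                for t in ("ad", "loe"))
        assert gaps[0.8][0] > gaps[0.4][0] > 0
        assert gaps[0.8][1] > gaps[0.4][1] > 0

    def test_no_misclassification_means_exact_labels(self, small_cohort):
        _, _, cohort, truth, _ = small_cohort
        assert (cohort["ad_case"].to_numpy()
                == truth.liabilities["true_ad"].to_numpy()).all()
        assert (cohort["loe_case"].to_numpy()
                == truth.liabilities["true_loe"].to_numpy()).all()

    def test_misclassification_rate_calibrated(self):
        rate = 0.1
        cfg = _config(n_individuals=20_000, n_snps=10,
                      misclassification_rate=rate)
        g, _ = simulate.simulate_genotypes(cfg)
        cohort, truth = simulate.simulate_phenotypes(g, cfg)
        flipped = (cohort["ad_case"].to_numpy()
                   != truth.liabilities["true_ad"].to_numpy()).mean()
        se = np.sqrt(rate * (1 - rate) / 20_000)
        assert abs(flipped - rate) < 2 * se

    def test_liability_reconstructable_from_truth(self, small_config,
                                                  small_cohort):
        genos, _, _, truth, _ = small_cohort
        B = small_config.beta_matrix()
        centered = genos.dosages - genos.dosages.mean(axis=0)
        lia = truth.liabilities
        planned = lia["planned_age_last_visit"].to_numpy()
        # reconstruct the AD liability exactly from stored components
        q = small_config.base_prevalence["ad"]
        eff = small_config.demographic_effects["ad"]
        # sex is not stored in truth; recover via cohort
        sex = small_cohort[2]["sex"].to_numpy()
        expected = (np.log(q / (1 - q)) + centered @ B[:, 0]
                    + eff["age"] * (planned - planned.mean())
                    + eff["sex"] * (sex - sex.mean()))
        np.testing.assert_allclose(lia["liability_ad"], expected,
                                   atol=1e-10)


class TestEncounters:
    def test_cases_get_trait_codes_at_valid_ages(self, small_cohort):
        _, _, cohort, _, enc = small_cohort
        loe_ids = set(cohort.loc[cohort["loe_case"] == 1, "patient_id"])
        loe_codes = enc[enc["icd10"].str.startswith("G40")]
        assert set(loe_codes["patient_id"]) == loe_ids
        assert (loe_codes["age"] > 60).all()
        ad_ids = set(cohort.loc[cohort["ad_case"] == 1, "patient_id"])
        ad_codes = enc[enc["icd10"].str.startswith("G30")]
        assert set(ad_codes["patient_id"]) == ad_ids

    def test_controls_have_no_trait_or_exclude_codes(self, small_cohort):
        _, _, cohort, _, enc = small_cohort
        controls = set(cohort.loc[(cohort["ad_case"] == 0)
                                  & (cohort["loe_case"] == 0),
                                  "patient_id"])
        bad = enc[enc["icd10"].str.startswith(("G30", "G40", "R56", "F0"))]
        assert not (set(bad["patient_id"]) & controls)

    def test_min_two_encounters_after_60(self, small_cohort):
        _, _, cohort, _, enc = small_cohort
        eligible = cohort.loc[(cohort["age_last_visit"] > 61)
                              & (cohort["sparse_record"] == 0),
                              "patient_id"]
        counts = enc[enc["age"] > 60].groupby("patient_id").size()
        assert (counts.reindex(eligible).fillna(0) >= 2).all()

    def test_missing_required_phecode_rejected(self, small_cohort,
                                               small_config):
        _, _, cohort, _, _ = small_cohort
        bad_map = phenotyping.PhecodeMap(entries=pd.DataFrame(
            [("G40.909", "345.1")], columns=["icd10", "phecode"]))
        with pytest.raises(ValueError, match="290.11"):
            simulate.simulate_encounters(cohort, bad_map, small_config)

    def test_empty_cohort_rejected(self, small_config):
        with pytest.raises(ValueError, match="empty"):
            simulate.simulate_encounters(
                pd.DataFrame(), phenotyping.PhecodeMap.default(),
                small_config)
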