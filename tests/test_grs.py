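"""Shared GRS construction and evaluation: standardization, association,
explained variance, AUPRC, Wilcoxon comparison, APOE-region variant."""

import numpy as np
import pandas as pd
import pytest

from adloe import grs
from adloe.grs import GrsModel
from adloe.metrics import auprc, compare_auprc


def _training_data(seed=0, n=500, p=4, beta=None):
    rng = np.random.default_rng(seed)
    D = pd.DataFrame(rng.binomial(2, 0.3, size=(n, p)).astype(float),
                     columns=[f"s{j}" for j in range(p)],
                     index=[f"i{k}" for k in range(n)])
    covs = np.column_stack([rng.uniform(60, 90, n), rng.integers(0, 2, n)])
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    logit = -2.0 + (D.to_numpy() - 0.6) @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    return D, covs, y


class TestWeightsAndScore:
    def test_training_scores_standardized(self):
        D, covs, y = _training_data(beta=[0.5, 0, 0, 0])
        model = grs.fit_grs_weights(D, list(D.columns), y, covs)
        s = grs.score(D, model)
        assert abs(s.mean()) < 1e-10
        assert s.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_single_snp_effect_recovered(self):
        hits = 0
        for seed in range(10):
            D, covs, y = _training_data(seed=seed, n=8000, p=1,
                                        beta=[0.5])
            model = grs.fit_grs_weights(D, ["s0"], y, covs)
            hits += abs(model.weights.iloc[0] - 0.5) <= 0.1
        assert hits >= 9

    def test_null_outcome_gives_small_weights(self):
        D, covs, y = _training_data(seed=3, n=5000)
        model = grs.fit_grs_weights(D, list(D.columns), y, covs)
        assert np.abs(model.weights).max() < 0.2

    def test_empty_shared_set_rejected(self):
        D, covs, y = _training_data()
        with pytest.raises(ValueError, match="empty"):
            grs.fit_grs_weights(D, [], y, covs)

    def test_zero_sd_model_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            GrsModel(snps=["s0"], weights=pd.Series([0.0], index=["s0"]),
                     train_mean=0.0, train_sd=0.0)

    def test_scaled_weights_leave_standardized_scores_unchanged(self):
        D, covs, y = _training_data(beta=[0.5, -0.3, 0, 0])
        m1 = grs.fit_grs_weights(D, list(D.columns), y, covs)
        w2 = m1.weights * 2
        raw2 = D.to_numpy() @ w2.to_numpy()
        m2 = GrsModel(snps=m1.snps, weights=w2,
                      train_mean=float(raw2.mean()),
                      train_sd=float(raw2.std(ddof=0)))
        np.testing.assert_allclose(grs.score(D, m1), grs.score(D, m2),
                                   atol=1e-10)

    def test_missing_snps_skipped_all_missing_rejected(self):
        D, covs, y = _training_data(beta=[0.5, 0, 0, 0])
        model = grs.fit_grs_weights(D, list(D.columns), y, covs)
        with pytest.warns(UserWarning, match="missing"):
            grs.score(D[["s0", "s1"]], model)
        with pytest.raises(ValueError, match="none"):
            grs.score(D[[]].assign(other=1.0), model)


class TestAssociation:
    def test_null_score_ci_covers_one(self):
        covered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 1000
            s = rng.normal(size=n)
            y = (rng.random(n) < 0.1).astype(float)
            covs = rng.normal(size=(n, 2))
            a = grs.test_association(s, y, covs)
            covered += a.ci_lower <= 1.0 <= a.ci_upper
        assert covered >= 9

    def test_true_positive_association_detected(self):
        rng = np.random.default_rng(42)
        n = 4000
        s = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(2.2 - 0.6 * s))).astype(float)
        a = grs.test_association(s, y, rng.normal(size=(n, 2)))
        assert a.odds_ratio > 1.3 and a.p_value < 1e-6
        assert a.explained_variance_pct > 0

    def test_perfect_predictor_raises_separation_error(self):
        n = 200
        s = np.linspace(-3, 3, n)
        y = (s > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            grs.test_association(s, y, np.ones((n, 1)) * 0.0
                                 + np.random.default_rng(0).normal(
                                     size=(n, 1)) * 1e-3)

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError, match="cases"):
            grs.test_association(np.ones(10), np.zeros(10),
                                 np.ones((10, 1)))


class TestExplainedVariance:
    def test_hand_values(self):
        assert grs.explained_variance(100.0, 80.0) == pytest.approx(20.0)
        assert grs.explained_variance(50.0, 50.0) == 0.0

    def test_zero_reduced_deviance_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            grs.explained_variance(0.0, 0.0)

    def test_null_data_explained_variance_near_zero(self):
        rng = np.random.default_rng(8)
        n = 5000
        s = rng.normal(size=n)
        y = (rng.random(n) < 0.2).astype(float)
        a = grs.test_association(s, y, rng.normal(size=(n, 2)))
        assert -0.5 <= a.explained_variance_pct <= 0.5


class TestAuprc:
    def test_perfect_ranking_is_one(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert auprc(y, s) == pytest.approx(1.0)

    def test_constant_scores_equal_prevalence(self):
        y = np.array([0, 1, 0, 0, 1, 0, 0, 0, 0, 0])
        assert auprc(y, np.ones(10)) == pytest.approx(0.2)

    def test_matches_bruteforce_threshold_enumeration(self, rng):
        def brute(y, s):
            n_pos = y.sum()
            pts = []
            for thr in sorted(set(s), reverse=True):
                pred = s >= thr
                tp = int((y & pred).sum())
                pts.append((tp / n_pos, tp / int(pred.sum())))
            area, prev_r = 0.0, 0.0
            for r, p in pts:
                area += (r - prev_r) * p
                prev_r = r
            return area

        for _ in range(50):
            n = int(rng.integers(4, 21))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 1)  # induce ties
            assert auprc(y, s) == pytest.approx(brute(y, s), abs=1e-12)

    def test_random_scores_average_to_prevalence(self, rng):
        n, q = 2000, 0.1
        vals = []
        for _ in range(40):
            y = (rng.random(n) < q).astype(int)
            vals.append(auprc(y, rng.random(n)))
        assert np.mean(vals) == pytest.approx(q, abs=0.02)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            auprc(np.zeros(5, dtype=int), np.random.rand(5))


class TestCompareAuprc:
    def test_identical_arrays_give_p_one(self):
        a = np.linspace(0.1, 0.5, 12)
        out = compare_auprc(a, a.copy())
        assert out["p_value"] == 1.0
        assert out["mean_difference"] == 0.0

    def test_systematic_improvement_detected(self, rng):
        b = rng.uniform(0.05, 0.15, size=30)
        a = b + 0.03
        out = compare_auprc(a, b)
        assert out["p_value"] < 0.01
        assert out["mean_a"] > out["mean_b"]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="5"):
            compare_auprc([0.1] * 4, [0.2] * 4)


class TestNonApoeVariant:
    def _annotation(self):
        return pd.DataFrame({
            "snp_id": ["in_apoe", "s_out1", "s_out2"],
            "chrom": ["19", "2", "8"],
            "pos": [44_900_000, 127_000_000, 27_600_000],
        })

    def test_window_snp_removed_and_weights_refit(self):
        rng = np.random.default_rng(1)
        D = pd.DataFrame(rng.binomial(2, 0.3, size=(600, 3)).astype(float),
                         columns=["in_apoe", "s_out1", "s_out2"])
        covs = rng.normal(size=(600, 2))
        y = (rng.random(600) < 0.15).astype(float)
        model = grs.fit_grs_weights(D, list(D.columns), y, covs)
        variant = grs.build_non_apoe_variant(model, self._annotation(),
                                             D, y, covs)
        assert variant.snps == ["s_out1", "s_out2"]
        assert variant.variant == "without_apoe"

    def test_no_chr19_snps_keeps_list(self):
        rng = np.random.default_rng(2)
        D = pd.DataFrame(rng.binomial(2, 0.3, size=(400, 2)).astype(float),
                         columns=["s_out1", "s_out2"])
        covs = rng.normal(size=(400, 2))
        y = (rng.random(400) < 0.15).astype(float)
        model = grs.fit_grs_weights(D, list(D.columns), y, covs)
        variant = grs.build_non_apoe_variant(model, self._annotation(),
                                             D, y, covs)
        assert variant.snps == model.snps

    def test_all_snps_in_window_rejected(self):
        rng = np.random.default_rng(3)
        D = pd.DataFrame(rng.binomial(2, 0.3, size=(300, 1)).astype(float),
                         columns=["in_apoe"])
        covs = rng.normal(size=(300, 2))
        y = (rng.random(300) < 0.15).astype(float)
        model = grs.fit_grs_weights(D, ["in_apoe"], y, covs)
        with pytest.raises(ValueError, match="remain"):
            grs.build_non_apoe_variant(model, self._annotation(), D, y,
                                       covs)
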