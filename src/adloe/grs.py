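"""Shared AD-LOE genetic risk score (GRS): weights, scoring, evaluation.

The shared GRS is built from the shared-risk SNPs found by the stability
analysis: per-SNP weights come from ONE joint logistic regression of the
combined "AD or LOE" outcome on all shared SNP dosages in the training
split, after demographic/PC effects are removed through a covariate
offset (exactly the offset construction used in the selection stage).
Scores are GRS_i = sum_j beta_j * dosage_ij, standardized to mean 0 /
SD 1 with training-set constants.  Evaluation (odds ratios per SD and
deviance-based explained variance) happens on the held-out split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genetics import _in_apoe_region

__all__ = [
    "GrsModel",
    "AssociationResult",
    "combined_outcome",
    "fit_grs_weights",
    "score",
    "test_association",
    "explained_variance",
    "build_non_apoe_variant",
]


@dataclass
class GrsModel:
    """Shared-risk SNP weights plus training-split standardization."""

    snps: list
    weights: pd.Series          # indexed by snp id, log-odds per dosage
    train_mean: float
    train_sd: float
    variant: str = "full"       # or "without_apoe"
    ridge_fallback: bool = False

    def __post_init__(self):
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite GRS weights")
        if not self.train_sd > 0:
            raise ValueError("degenerate GRS: training-score SD is zero")


def combined_outcome(cohort: pd.DataFrame) -> pd.Series:
    """The union 'AD or LOE' case indicator; patients excluded for either
    trait are dropped (NaN) so they do not enter the combined analysis."""
    ad = cohort["ad_status"] if "ad_status" in cohort.columns else None
    if ad is not None:
        ok = (cohort["ad_status"] != "excluded") & \
             (cohort["loe_status"] != "excluded")
        y = ((cohort["ad_status"] == "case")
             | (cohort["loe_status"] == "case")).astype(float)
        return y.where(ok)
    return ((cohort["ad_case"] == 1) | (cohort["loe_case"] == 1)) \
        .astype(float)


def _offset_eta(y, covariates):
    Xd = sm.add_constant(np.asarray(covariates, dtype=float),
                         has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and \
                    np.all(np.abs(res.params) < 30):
                return Xd @ res.params
        except Exception:
            pass
        glm = sm.GLM(y, Xd, family=sm.families.Binomial())
        return Xd @ glm.fit_regularized(alpha=1e-6, L1_wt=0.0).params


def fit_grs_weights(dosages: pd.DataFrame, shared_snps: list,
                    y: np.ndarray, covariates: np.ndarray,
                    variant: str = "full") -> GrsModel:
    """Estimate shared-GRS weights on the training split.

    ``dosages`` is a samples x SNPs frame.  One joint logistic fit of the
    combined outcome on all shared SNP dosages, with the covariate-only
    linear predictor entering as a fixed offset; quasi-separation falls
    back to a tiny ridge penalty.
    """
    shared_snps = list(shared_snps)
    if not shared_snps:
        raise ValueError("shared-risk SNP set is empty")
    D = dosages[shared_snps].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    eta = _offset_eta(y, covariates)
    Xd = sm.add_constant(D, has_constant="add")
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, Xd, family=sm.families.Binomial(),
                         offset=eta).fit(maxiter=200)
            params = res.params
            if not np.all(np.isfinite(params)) or \
                    np.any(np.abs(params[1:]) > 30):
                raise ValueError("unstable fit")
        except Exception:
            glm = sm.GLM(y, Xd, family=sm.families.Binomial(), offset=eta)
            params = glm.fit_regularized(alpha=1e-6, L1_wt=0.0).params
            fallback = True
    weights = pd.Series(params[1:], index=shared_snps, name="beta")
    raw = D @ weights.to_numpy()
    return GrsModel(snps=shared_snps, weights=weights,
                    train_mean=float(raw.mean()),
                    train_sd=float(raw.std(ddof=0)),
                    variant=variant, ridge_fallback=fallback)


def score(dosages: pd.DataFrame, model: GrsModel) -> pd.Series:
    """Standardized per-sample GRS, (sum_j beta_j dosage_ij - train mean)
    / train SD.  SNPs absent from ``dosages`` are skipped with a warning;
    an empty intersection is an error."""
    present = [s for s in model.snps if s in dosages.columns]
    if not present:
        raise ValueError("none of the model SNPs are present")
    if len(present) < len(model.snps):
        warnings.warn(f"{len(model.snps) - len(present)} model SNPs missing "
                      "from dosage table; skipped")
    raw = dosages[present].to_numpy(dtype=float) @ \
        model.weights.loc[present].to_numpy()
    std = (raw - model.train_mean) / model.train_sd
    return pd.Series(std, index=dosages.index, name="grs")


@dataclass
class AssociationResult:
    phenotype: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    explained_variance_pct: float
    n: int


def explained_variance(dev_reduced: float, dev_full: float) -> float:
    """Percent of outcome deviance explained by adding the score:
    100 * (dev_reduced - dev_full) / dev_reduced."""
    if dev_reduced < 0 or dev_full < 0:
        raise ValueError("deviances must be non-negative")
    if dev_reduced == 0:
        raise ValueError("reduced-model deviance is zero")
    return 100.0 * (dev_reduced - dev_full) / dev_reduced


def test_association(scores, phenotype, covariates,
                     label: str = "") -> AssociationResult:
    """Logistic association of a genetic score (or ε4 count) with a
    phenotype on the evaluation split, adjusted for the supplied
    covariates; reports the OR per score unit with Wald CI and the
    deviance-based explained variance."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("phenotype has no cases (or no controls) "
                         "in the evaluation split")
    X_full = sm.add_constant(np.column_stack([s, C]), has_constant="add")
    X_red = sm.add_constant(C, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit()
        red = sm.GLM(y, X_red, family=sm.families.Binomial()).fit()
    beta = full.params[1]
    se = full.bse[1]
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30:
        raise ValueError("separation in the association model")
    return AssociationResult(
        phenotype=label,
        odds_ratio=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - 1.96 * se)),
        ci_upper=float(np.exp(beta + 1.96 * se)),
        p_value=float(full.pvalues[1]),
        explained_variance_pct=explained_variance(red.deviance,
                                                  full.deviance),
        n=len(y))


def build_non_apoe_variant(model: GrsModel, annotation: pd.DataFrame,
                           dosages_train: pd.DataFrame, y_train,
                           covariates_train) -> GrsModel:
    """Sensitivity variant without the chr19 TOMM40--APOE--APOC1 window:
    drops shared SNPs inside the window and refits the weights on the
    training split."""
    ann = annotation.set_index("snp_id")
    inside = pd.Series(_in_apoe_region(annotation),
                       index=ann.index)
    keep = [s for s in model.snps if not bool(inside.get(s, False))]
    if not keep:
        raise ValueError("no shared SNPs remain outside the APOE region")
    return fit_grs_weights(dosages_train, keep, y_train, covariates_train,
                           variant="without_apoe")
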