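"""Stability resampling around the multi-task elastic net.

The selection pipeline (train/test split -> covariate offset model ->
hyperparameter grid search -> multi-task fit) is repeated over many
seeded iterations; SNPs selected in at least a fixed fraction of
iterations (default 25%) are retained, and those whose across-iteration
mean coefficients have the same sign for both tasks form the shared-risk
set.  Per-iteration test-set AUPRCs are recorded for the multi-task fit
and for single-task baselines so the two can be compared downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import multitask as mt
from .metrics import auprc

__all__ = [
    "StabilityResult",
    "run_iterations",
    "select_stable",
    "identify_shared",
    "magnitude_report",
]

TASKS = ("ad", "loe")


@dataclass
class StabilityResult:
    snp_ids: list
    n_iter: int
    n_success: int
    selection_count: np.ndarray      # p
    coef_sum: np.ndarray             # p x T, summed over iterations
    auprc_mt: np.ndarray             # n_success x T
    auprc_st: np.ndarray             # n_success x T
    seeds: list
    failures: list = field(default_factory=list)

    @property
    def selection_frequency(self) -> np.ndarray:
        return self.selection_count / max(self.n_success, 1)

    @property
    def mean_coef(self) -> np.ndarray:
        """Mean per-task coefficient across iterations (zeros included)."""
        return self.coef_sum / max(self.n_success, 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids,
                           "selection_frequency": self.selection_frequency})
        for t, task in enumerate(TASKS[:self.coef_sum.shape[1]]):
            df[f"coef_{task}"] = self.mean_coef[:, t]
        return df


def _stratified_split(rng, y, split_fraction):
    """Train/test indices, stratified on the joint task labels when each
    stratum has at least two members."""
    from sklearn.model_selection import train_test_split

    n = y.shape[0]
    joint = (y * (2 ** np.arange(y.shape[1]))).sum(axis=1)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    _, counts = np.unique(joint, return_counts=True)
    strat = joint if counts.min() >= 2 else None
    return train_test_split(np.arange(n), train_size=split_fraction,
                            random_state=seed, stratify=strat)


def _one_iteration(X, covariates, y, rng, split_fraction, rho_grid,
                   n_alphas, alpha_decades, folds, tol, max_iter,
                   resample):
    if resample == "split":
        tr, te = _stratified_split(rng, y, split_fraction)
    elif resample == "bootstrap":
        n = y.shape[0]
        tr = rng.integers(0, n, size=n)
        te = np.setdiff1d(np.arange(n), np.unique(tr))
    else:
        raise ValueError(f"unknown resampling scheme: {resample!r}")

    offset = mt.fit_offset_model(covariates[tr], y[tr])
    R = offset.residuals
    Xs, mean, std = mt.standardize(X[tr])
    Xs_te = (X[te] - mean) / std
    eta_te = offset.eta_for(covariates[te])

    rho_max = max(rho_grid)
    alpha_grid = mt.default_alpha_grid(Xs, R, rho_max, n_alphas=n_alphas,
                                       decades=alpha_decades)
    gs_seed = int(rng.integers(0, 2 ** 31 - 1))
    gram_cache = {}
    best_a, best_r, _ = mt.grid_search(Xs, R, alpha_grid, rho_grid,
                                       folds=folds, seed=gs_seed, tol=tol,
                                       max_iter=max_iter,
                                       gram_cache=gram_cache)
    fit = mt.fit_mt_enet(Xs, R, best_a, best_r, tol=tol, max_iter=max_iter)
    probs = mt.predict(fit, Xs_te, eta_te)
    T = y.shape[1]
    ap_mt = np.array([auprc(y[te][:, t], probs[:, t]) for t in range(T)])

    ap_st = np.empty(T)
    W_st = np.empty_like(fit.W)
    for t in range(T):
        a_t, r_t, _ = mt.grid_search(Xs, R[:, [t]], alpha_grid, rho_grid,
                                     folds=folds, seed=gs_seed, tol=tol,
                                     max_iter=max_iter,
                                     gram_cache=gram_cache)
        fit_t = mt.fit_mt_enet(Xs, R[:, [t]], a_t, r_t, tol=tol,
                               max_iter=max_iter)
        W_st[:, t] = fit_t.W[:, 0]
        p_t = mt.predict(fit_t, Xs_te, eta_te[:, [t]])
        ap_st[t] = auprc(y[te][:, t], p_t[:, 0])
    return fit, ap_mt, ap_st, W_st


def run_iterations(X, covariates, y, n_iter: int = 1000,
                   base_seed: int = 0, split_fraction: float = 0.8,
                   snp_ids=None, rho_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
                   n_alphas: int = 20, alpha_decades: float = 3.0,
                   folds: int = 5, tol: float = 1e-6,
                   max_iter: int = 10_000,
                   resample: str = "split") -> StabilityResult:
    """Repeat the full selection pipeline over seeded resamples.

    Each iteration draws a fresh stratified 80/20 train/test split (or a
    bootstrap resample), refits the covariate offset model, re-runs the
    hyperparameter grid search, fits the multi-task elastic net on the
    training part, and records which coefficient rows are nonzero along
    with test-set AUPRCs (multi-task and single-task).  Fully
    reproducible from ``base_seed``.  Iterations that fail are skipped;
    more than 10% failures aborts the run.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.ndim == 1:
        y = y[:, None]
    n, p = X.shape
    T = y.shape[1]
    snp_ids = list(snp_ids) if snp_ids is not None \
        else [f"snp{j:04d}" for j in range(p)]

    children = np.random.SeedSequence(base_seed).spawn(n_iter)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]

    sel = np.zeros(p)
    coef_sum = np.zeros((p, T))
    ap_mt_all, ap_st_all = [], []
    failures = []
    for i in range(n_iter):
        rng = np.random.default_rng(children[i])
        try:
            fit, ap_mt, ap_st, _ = _one_iteration(
                X, covariates, y, rng, split_fraction, rho_grid, n_alphas,
                alpha_decades, folds, tol, max_iter, resample)
        except Exception as exc:  # recorded, not fatal
            failures.append((i, repr(exc)))
            continue
        nz = np.any(fit.W != 0.0, axis=1)
        sel[nz] += 1
        coef_sum += fit.W
        ap_mt_all.append(ap_mt)
        ap_st_all.append(ap_st)
    n_success = n_iter - len(failures)
    if len(failures) > 0.1 * n_iter:
        raise RuntimeError(f"{len(failures)}/{n_iter} stability iterations "
                           f"failed; first: {failures[0]}")
    return StabilityResult(
        snp_ids=snp_ids, n_iter=n_iter, n_success=n_success,
        selection_count=sel, coef_sum=coef_sum,
        auprc_mt=np.array(ap_mt_all).reshape(n_success, T),
        auprc_st=np.array(ap_st_all).reshape(n_success, T),
        seeds=seeds, failures=failures)


def select_stable(result: StabilityResult,
                  threshold: float = 0.25) -> list:
    """SNPs selected in at least ``threshold`` of the iterations."""
    keep = result.selection_frequency >= threshold
    return [s for s, k in zip(result.snp_ids, keep) if k]


def identify_shared(result: StabilityResult, retained: list,
                    annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Shared-risk SNPs: retained SNPs whose mean coefficients are nonzero
    and same-sign for both tasks.  Returns one row per shared SNP with
    frequency, per-task mean coefficients, direction and (when annotation
    is given) the source-trait label."""
    unknown = set(retained) - set(result.snp_ids)
    if unknown:
        raise ValueError(f"retained SNPs not in result: {sorted(unknown)}")
    idx = {s: j for j, s in enumerate(result.snp_ids)}
    mean = result.mean_coef
    freq = result.selection_frequency
    rows = []
    for s in retained:
        j = idx[s]
        c_ad, c_loe = mean[j, 0], mean[j, 1]
        if c_ad == 0.0 or c_loe == 0.0 or np.sign(c_ad) != np.sign(c_loe):
            continue
        rows.append({
            "snp_id": s,
            "selection_frequency": float(freq[j]),
            "coef_ad": float(c_ad),
            "coef_loe": float(c_loe),
            "direction": "+" if c_ad > 0 else "-",
        })
    shared = pd.DataFrame(rows, columns=["snp_id", "selection_frequency",
                                         "coef_ad", "coef_loe",
                                         "direction"])
    if annotation is not None and not shared.empty:
        src = annotation.set_index("snp_id")["source_trait"]
        shared["source_trait"] = shared["snp_id"].map(src)
    return shared


def magnitude_report(shared: pd.DataFrame) -> pd.DataFrame:
    """Shared SNPs ranked by the larger per-task standardized coefficient
    magnitude (ties broken by SNP id)."""
    if shared.empty:
        raise ValueError("shared-risk set is empty")
    out = shared.copy()
    out["magnitude_ad"] = out["coef_ad"].abs()
    out["magnitude_loe"] = out["coef_loe"].abs()
    out["magnitude"] = out[["magnitude_ad", "magnitude_loe"]].max(axis=1)
    out = out.sort_values(["magnitude", "snp_id"],
                          ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
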