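"""Bidirectional time-to-event association between LOE and AD.

Builds per-patient survival records on the age timescale with delayed
entry at the first visit (all eligibility rules are age-based; a
time-on-study axis is available as an option), then fits

* cause-specific Cox proportional hazards (deaths censored), and
* Fine--Gray subdistribution hazards, in which subjects who die remain
  in later risk sets with inverse-probability-of-censoring (IPCW)
  weights from a Kaplan--Meier estimate of the censoring distribution,
  so the estimate targets the cumulative incidence of the outcome.

Exposure is classified at baseline; patients whose outcome precedes the
exposure onset are excluded (their ordering contradicts an
exposure->outcome reading), and the removal count is reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter

__all__ = [
    "BASIC_COVARIATES",
    "build_survival_records",
    "fit_cox",
    "fit_fine_gray",
    "simulate_exponential_cohort",
]

#: The basic adjustment set: demographics plus shared comorbidities.
BASIC_COVARIATES = ["age_first_visit", "sex", "record_length",
                    "hypertension", "diabetes", "stroke", "hyperlipidemia"]


def _case_flag(cohort: pd.DataFrame, trait: str) -> pd.Series:
    col = f"{trait}_status"
    if col in cohort.columns:
        return (cohort[col] == "case").astype(int)
    return cohort[f"{trait}_case"].astype(int)


def _not_excluded(cohort: pd.DataFrame, trait: str) -> pd.Series:
    col = f"{trait}_status"
    if col in cohort.columns:
        return cohort[col] != "excluded"
    return pd.Series(True, index=cohort.index)


def build_survival_records(cohort: pd.DataFrame, exposure_trait: str,
                           outcome_trait: str,
                           extra_covariates: list | None = None):
    """Assemble one survival record per eligible patient.

    Entry is the age at first visit (floored at 60); exit is the first of
    outcome onset, death and last visit, and the event type is set
    accordingly.  Exposed patients whose outcome onset precedes the
    exposure onset are removed.  Returns (records, n_removed).
    """
    if exposure_trait == outcome_trait:
        raise ValueError("exposure and outcome traits must differ")
    c = cohort.loc[_not_excluded(cohort, exposure_trait)
                   & _not_excluded(cohort, outcome_trait)].copy()
    exposed = _case_flag(c, exposure_trait)
    has_outcome = _case_flag(c, outcome_trait)
    onset_exp = c[f"{exposure_trait}_onset_age"]
    onset_out = c[f"{outcome_trait}_onset_age"]

    entry = np.maximum(c["age_first_visit"].to_numpy(dtype=float), 60.0)
    death_age = c.get("death_age", pd.Series(np.nan, index=c.index))
    deceased = c.get("deceased", pd.Series(0, index=c.index)).fillna(0)
    last = c["age_last_visit"].to_numpy(dtype=float)

    exit_age = last.copy()
    event = np.array(["censored"] * len(c), dtype=object)
    death_exit = np.where(deceased.astype(bool), death_age, np.inf)
    out_exit = np.where(has_outcome.astype(bool), onset_out, np.inf)
    for i in range(len(c)):
        t = min(out_exit[i], death_exit[i], last[i])
        exit_age[i] = t
        if t == out_exit[i]:
            event[i] = "outcome"
        elif t == death_exit[i]:
            event[i] = "death"

    bad_order = (exposed.to_numpy(dtype=bool)
                 & has_outcome.to_numpy(dtype=bool)
                 & (onset_out.to_numpy(dtype=float)
                    < onset_exp.to_numpy(dtype=float)))
    keep = ~bad_order & (exit_age > entry)
    n_removed = int(bad_order.sum())

    covs = list(extra_covariates or [])
    records = pd.DataFrame({
        "patient_id": c["patient_id"].to_numpy(),
        "entry_age": entry,
        "exit_age": exit_age,
        "event_type": event,
        "exposed": exposed.to_numpy(),
    })
    for var in BASIC_COVARIATES + covs:
        if var in c.columns:
            records[var] = c[var].to_numpy()
    return records.loc[keep].reset_index(drop=True), n_removed


def _check_records(records, covariates):
    if (records["event_type"] == "outcome").sum() < 1:
        raise ValueError("no outcome events in the records")
    for v in covariates:
        if records[v].nunique() <= 1:
            raise ValueError(f"constant covariate: {v}")


def _summary_to_estimates(summary: pd.DataFrame, model: str) -> pd.DataFrame:
    out = pd.DataFrame({
        "covariate": summary.index,
        "hr": np.exp(summary["coef"]).to_numpy(),
        "ci_lower": np.exp(summary["coef"]
                           - 1.96 * summary["se(coef)"]).to_numpy(),
        "ci_upper": np.exp(summary["coef"]
                           + 1.96 * summary["se(coef)"]).to_numpy(),
        "coef": summary["coef"].to_numpy(),
        "se": summary["se(coef)"].to_numpy(),
        "p_value": summary["p"].to_numpy(),
        "model": model,
    })
    return out.reset_index(drop=True)


def fit_cox(records: pd.DataFrame, covariates: list | None = None,
            timescale: str = "age") -> pd.DataFrame:
    """Cause-specific Cox model (Efron ties); deaths are censored.

    ``timescale='age'`` uses age with delayed entry (left truncation);
    ``'study'`` uses time since first visit.
    """
    covariates = [v for v in (covariates if covariates is not None
                              else BASIC_COVARIATES)
                  if v in records.columns]
    _check_records(records, covariates)
    df = records[["exposed"] + covariates].copy()
    df["event"] = (records["event_type"] == "outcome").astype(int)
    if timescale == "age":
        df["entry"] = records["entry_age"]
        df["exit"] = records["exit_age"]
        kw = dict(duration_col="exit", event_col="event",
                  entry_col="entry")
    elif timescale == "study":
        df["duration"] = records["exit_age"] - records["entry_age"]
        kw = dict(duration_col="duration", event_col="event")
    else:
        raise ValueError(f"unknown timescale: {timescale!r}")
    cph = _fit_with_ridge_fallback(CoxPHFitter, df, kw)
    return _summary_to_estimates(cph.summary, "cox")


def _fit_with_ridge_fallback(fitter_cls, df, kw):
    """Newton steps can stall on sparse covariates (quasi-separation);
    retry once with a small L2 penalty."""
    from lifelines.exceptions import ConvergenceError

    try:
        fitter = fitter_cls()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, **kw)
        return fitter
    except ConvergenceError:
        fitter = fitter_cls(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, **kw)
        warnings.warn("Cox fit needed an L2 penalty (0.1) to converge",
                      RuntimeWarning)
        return fitter


def _censoring_survival(records: pd.DataFrame) -> KaplanMeierFitter:
    """KM estimate of the censoring distribution G (censoring = event)."""
    km = KaplanMeierFitter()
    km.fit(records["exit_age"],
           event_observed=(records["event_type"] == "censored").astype(int),
           entry=records["entry_age"])
    return km


def finegray_expand(records: pd.DataFrame, covariates: list,
                    max_breaks: int = 60) -> pd.DataFrame:
    """Counting-process expansion for the Fine--Gray model.

    Subjects without the competing event contribute their original
    at-risk interval.  Subjects who die are retained in the risk set
    after death: their interval is extended across subsequent outcome
    event times with IPCW weights G(t)/G(t_death).  When there are more
    distinct event times than ``max_breaks`` the weight-update grid is
    coarsened to event-time quantiles, keeping the expansion near-linear
    in cohort size (weights change little between adjacent breaks).
    """
    event_times = np.sort(records.loc[records["event_type"] == "outcome",
                                      "exit_age"].unique())
    if len(event_times) > max_breaks:
        qs = np.linspace(0, 1, max_breaks)
        event_times = np.unique(np.quantile(event_times, qs))
    km = _censoring_survival(records)

    def G(t):
        return float(km.predict(t))

    rows = []
    for i, rec in enumerate(records.itertuples(index=False)):
        base = {v: getattr(rec, v) for v in ["exposed"] + covariates}
        rows.append({**base, "id": i, "start": rec.entry_age,
                     "stop": rec.exit_age,
                     "event": int(rec.event_type == "outcome"),
                     "w": 1.0})
        if rec.event_type != "death":
            continue
        g_death = G(rec.exit_age)
        if g_death <= 0:
            continue
        later = event_times[event_times > rec.exit_age]
        prev = rec.exit_age
        for t in later:
            w = G(t) / g_death
            if w <= 0:
                break
            rows.append({**base, "id": i, "start": prev, "stop": t,
                         "event": 0, "w": w})
            prev = t
    return pd.DataFrame(rows)


def fit_fine_gray(records: pd.DataFrame,
                  covariates: list | None = None) -> pd.DataFrame:
    """Fine--Gray subdistribution hazards via weighted Cox on the
    expanded risk sets.  With zero competing events this reduces exactly
    to :func:`fit_cox`."""
    covariates = [v for v in (covariates if covariates is not None
                              else BASIC_COVARIATES)
                  if v in records.columns]
    _check_records(records, covariates)
    expanded = finegray_expand(records, covariates)
    ctv = _fit_with_ridge_fallback(
        CoxTimeVaryingFitter, expanded,
        dict(id_col="id", event_col="event", start_col="start",
             stop_col="stop", weights_col="w"))
    return _summary_to_estimates(ctv.summary, "fine_gray")


# ---------------------------------------------------------------------------
# calibration utilities


def simulate_exponential_cohort(n: int, hr: float, seed: int,
                                base_hazard: float = 0.05,
                                death_hazard: float = 0.0,
                                death_hr: float = 1.0,
                                admin_censor: float = 30.0) -> pd.DataFrame:
    """Two-group exponential survival data with optional competing death.

    Used by the calibration suites: a binary exposure multiplies the
    outcome hazard by ``hr`` (and the death hazard by ``death_hr``);
    follow-up is administratively censored.  Times are reported on an
    age-like axis starting at 60 so the records slot into the fitters.
    """
    rng = np.random.default_rng(seed)
    exposed = rng.integers(0, 2, size=n)
    t_out = rng.exponential(1.0 / (base_hazard * hr ** exposed))
    if death_hazard > 0:
        t_death = rng.exponential(1.0 / (death_hazard
                                         * death_hr ** exposed))
    else:
        t_death = np.full(n, np.inf)
    t = np.minimum.reduce([t_out, t_death, np.full(n, admin_censor)])
    event = np.where(t == t_out, "outcome",
                     np.where(t == t_death, "death", "censored"))
    return pd.DataFrame({
        "patient_id": [f"s{i}" for i in range(n)],
        "entry_age": 60.0,
        "exit_age": 60.0 + t,
        "event_type": event,
        "exposed": exposed,
    })
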