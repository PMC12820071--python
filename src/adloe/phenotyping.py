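"""Phecode phenotyping of ICD-10 encounter streams.

Implements the EHR case/control logic for Alzheimer's disease (AD) and
late-onset epilepsy (LOE): ICD-10 codes are grouped into phecodes, cases
are defined by trait phecodes (with LOE additionally requiring first
diagnosis after age 60 and at least one encounter before 60), and
controls must be free of both the trait phecodes and their "exclude
ranges" — related phecodes that would contaminate the control group
(e.g. vascular dementia for AD).  Everyone else is excluded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhecodeMap",
    "LOE_PHECODES",
    "AD_PHECODE",
    "COMORBIDITY_PHECODES",
    "map_icd_to_phecodes",
    "define_loe_status",
    "define_ad_status",
    "assemble_cohort",
    "apply_cohort_filters",
    "descriptive_stats",
    "round_percent",
]

#: Phecodes defining LOE: epilepsy, recurrent seizures and convulsions.
LOE_PHECODES = {"345", "345.1", "345.11", "345.12", "345.3"}
#: Phecode defining AD (Alzheimer's disease).
AD_PHECODE = "290.11"
#: Comorbidity phecodes: >= 1 encounter each sets the flag.
COMORBIDITY_PHECODES = {"hypertension": "401.1", "diabetes": "250.2",
                        "stroke": "433", "hyperlipidemia": "272.1"}

_ICD10_RE = re.compile(r"^[A-TV-Z][0-9][0-9A-Z](\.[0-9A-Z]{1,4})?$")

#: Default ICD-10 -> phecode entries covering the codes this pipeline
#: needs; a full PheWAS-catalog map can be supplied instead.
_DEFAULT_ENTRIES = [
    ("G30.0", "290.11"), ("G30.1", "290.11"), ("G30.8", "290.11"),
    ("G30.9", "290.11"),
    ("F02.80", "290.12"), ("F01.50", "290.16"), ("F01.51", "290.16"),
    ("G40.901", "345"), ("G40.909", "345.1"), ("G40.309", "345.11"),
    ("G40.209", "345.12"), ("R56.9", "345.3"),
    ("I10", "401.1"), ("E11.9", "250.2"), ("I63.9", "433"),
    ("E78.5", "272.1"),
]

_DEFAULT_EXCLUDE_RANGES = {
    "ad": ["290-290.99"],
    "loe": ["345-345.99"],
}


def _parse_range(rng: str) -> tuple[float, float]:
    lo_s, hi_s = rng.split("-")
    lo, hi = float(lo_s), float(hi_s)
    if math.isnan(lo) or math.isnan(hi) or lo > hi:
        raise ValueError(f"malformed phecode range: {rng!r}")
    return lo, hi


@dataclass
class PhecodeMap:
    """ICD-10 -> phecode multimap plus per-trait exclude ranges."""

    entries: pd.DataFrame                      # columns icd10, phecode
    exclude_ranges: dict = field(
        default_factory=lambda: dict(_DEFAULT_EXCLUDE_RANGES))

    def __post_init__(self):
        self.entries = self.entries[["icd10", "phecode"]].astype(str)
        for trait, ranges in self.exclude_ranges.items():
            for rng in ranges:
                _parse_range(rng)  # validates

    @classmethod
    def default(cls) -> "PhecodeMap":
        return cls(entries=pd.DataFrame(_DEFAULT_ENTRIES,
                                        columns=["icd10", "phecode"]))

    @classmethod
    def from_csv(cls, path, exclude_ranges=None) -> "PhecodeMap":
        """Read a PheWAS-catalog style CSV with columns icd10, phecode."""
        df = pd.read_csv(path, dtype=str)
        kw = {} if exclude_ranges is None else {
            "exclude_ranges": exclude_ranges}
        return cls(entries=df.rename(columns=str.lower), **kw)

    def in_exclude_range(self, trait: str, phecode: str) -> bool:
        try:
            value = float(phecode)
        except ValueError:
            return False
        return any(lo <= value <= hi
                   for lo, hi in map(_parse_range,
                                     self.exclude_ranges[trait]))


# ---------------------------------------------------------------------------
# ICD mapping


def map_icd_to_phecodes(encounters: pd.DataFrame, pmap: PhecodeMap):
    """Join encounters to the phecode map.

    Emits one event per (encounter, matching map entry) — an ICD code
    mapping to several phecodes yields several events.  Unmapped codes
    produce no events; malformed ICD strings are rejected.  Both are
    tallied in the returned log dict.
    """
    codes = encounters["icd10"].astype(str)
    ok = codes.str.match(_ICD10_RE)
    log = {"n_malformed": int((~ok).sum()), "n_unmapped": 0}
    enc = encounters.loc[ok, ["patient_id", "age", "icd10"]]
    events = enc.merge(pmap.entries, on="icd10", how="left")
    unmapped = events["phecode"].isna()
    # count unmatched *encounters*, not map rows
    log["n_unmapped"] = int(unmapped.sum())
    events = events.loc[~unmapped, ["patient_id", "phecode", "age"]]
    return events.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# case/control status


def _exclude_mask(events: pd.DataFrame, pmap: PhecodeMap,
                  trait: str) -> pd.Series:
    uniq = {ph: pmap.in_exclude_range(trait, ph)
            for ph in events["phecode"].unique()}
    return events["phecode"].map(uniq)


def define_loe_status(events: pd.DataFrame,
                      encounters: pd.DataFrame,
                      pmap: PhecodeMap | None = None) -> pd.Series:
    """LOE status per patient: 'case', 'control' or 'excluded'.

    Case: >= 1 LOE-phecode event, the earliest one strictly after age 60,
    and >= 1 encounter (of any kind) before age 60.  Control: no LOE
    phecodes and nothing in the LOE exclude ranges.  Otherwise excluded.
    """
    pmap = pmap or PhecodeMap.default()
    patients = pd.Index(encounters["patient_id"].unique())
    first_enc = encounters.groupby("patient_id")["age"].min()

    is_loe = events["phecode"].isin(LOE_PHECODES)
    first_loe = events.loc[is_loe].groupby("patient_id")["age"].min()
    has_excl = events.loc[_exclude_mask(events, pmap, "loe")] \
        .groupby("patient_id").size()

    status = pd.Series("control", index=patients, name="loe_status")
    status[status.index.isin(has_excl.index)] = "excluded"
    case = first_loe[(first_loe > 60.0)
                     & (first_enc.reindex(first_loe.index) < 60.0)].index
    status[status.index.isin(case)] = "case"
    return status


def define_ad_status(events: pd.DataFrame,
                     encounters: pd.DataFrame,
                     pmap: PhecodeMap | None = None) -> pd.Series:
    """AD status per patient: one encounter with phecode 290.11 makes a
    case; controls must also be free of the 290 exclude range (e.g.
    vascular dementia 290.16); otherwise excluded."""
    pmap = pmap or PhecodeMap.default()
    patients = pd.Index(encounters["patient_id"].unique())
    cases = events.loc[events["phecode"] == AD_PHECODE, "patient_id"].unique()
    has_excl = events.loc[_exclude_mask(events, pmap, "ad"),
                          "patient_id"].unique()
    status = pd.Series("control", index=patients, name="ad_status")
    status[status.index.isin(has_excl)] = "excluded"
    status[status.index.isin(cases)] = "case"
    return status


def assemble_cohort(encounters: pd.DataFrame,
                    demographics: pd.DataFrame,
                    pmap: PhecodeMap | None = None) -> pd.DataFrame:
    """Build the per-patient cohort table from an encounter stream.

    ``demographics`` needs columns patient_id and sex, optionally
    deceased/death_age.  Visit ages, record length, phenotype statuses,
    onset ages and comorbidity flags are all derived from encounters.
    """
    pmap = pmap or PhecodeMap.default()
    events, _ = map_icd_to_phecodes(encounters, pmap)
    by_pt = encounters.groupby("patient_id")["age"]
    cohort = pd.DataFrame({
        "age_first_visit": by_pt.min(),
        "age_last_visit": by_pt.max(),
        "n_encounters_after_60": by_pt.apply(lambda a: int((a > 60).sum())),
    })
    cohort["record_length"] = (cohort["age_last_visit"]
                               - cohort["age_first_visit"])
    cohort["ad_status"] = define_ad_status(events, encounters, pmap)
    cohort["loe_status"] = define_loe_status(events, encounters, pmap)
    ad_onset = events.loc[events["phecode"] == AD_PHECODE] \
        .groupby("patient_id")["age"].min()
    loe_onset = events.loc[events["phecode"].isin(LOE_PHECODES)] \
        .groupby("patient_id")["age"].min()
    cohort["ad_onset_age"] = ad_onset.where(cohort["ad_status"] == "case")
    cohort["loe_onset_age"] = loe_onset.where(cohort["loe_status"] == "case")
    for flag, phecode in COMORBIDITY_PHECODES.items():
        carriers = events.loc[events["phecode"] == phecode,
                              "patient_id"].unique()
        cohort[flag] = cohort.index.isin(carriers).astype(int)
    cohort = cohort.join(
        demographics.set_index("patient_id"), how="left")
    return cohort.reset_index().rename(columns={"index": "patient_id"})


def apply_cohort_filters(cohort: pd.DataFrame,
                         mode: str = "full") -> pd.DataFrame:
    """Eligibility filters for the analytical samples.

    ``full``: complete demographics, >= 2 encounters after age 60, and
    last-visit age within [60, 90].  ``modeling``: additionally requires
    controls (for both traits) to have age at last visit >= 70 and at
    least five years of records; cases are exempt, and patients excluded
    for either trait are dropped so both task labels are binary.
    """
    if mode not in {"full", "modeling"}:
        raise ValueError(f"unknown filter mode: {mode!r}")
    c = cohort
    keep = (c["sex"].notna()
            & c["age_first_visit"].notna()
            & c["age_last_visit"].notna()
            & (c["n_encounters_after_60"] >= 2)
            & (c["age_last_visit"] >= 60.0)
            & (c["age_last_visit"] <= 90.0))
    if mode == "modeling":
        is_case = (c["ad_status"] == "case") | (c["loe_status"] == "case")
        is_excluded = ((c["ad_status"] == "excluded")
                       | (c["loe_status"] == "excluded"))
        strict = (c["age_last_visit"] >= 70.0) & (c["record_length"] >= 5.0)
        keep &= ~is_excluded & (is_case | strict)
    return c.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# descriptive statistics


def round_percent(k: int, n: int) -> float:
    """Percentage 100*k/n rounded to two significant figures, the printed
    precision of the cohort tables (571/7,351 -> 7.8; 44/376 -> 12)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * k / n
    if pct == 0.0:
        return 0.0
    decimals = 1 - int(math.floor(math.log10(abs(pct))))
    return round(pct, min(decimals, 10))


_CATEGORICAL = ["sex", "deceased", "hypertension", "diabetes", "stroke",
                "hyperlipidemia"]
_CONTINUOUS = ["age_first_visit", "age_last_visit", "record_length"]


def descriptive_stats(cohort: pd.DataFrame, stratify_by: str) -> pd.DataFrame:
    """Case/control summary table for one trait.

    Categorical variables: n (%) with Pearson chi-square p-values;
    continuous: mean (SD) with Wilcoxon rank-sum p-values.  The other
    trait's case indicator is included as a primary-outcome row.
    """
    status_col = f"{stratify_by}_status"
    if status_col not in cohort.columns:
        raise ValueError(f"no status column for trait {stratify_by!r}")
    cases = cohort[cohort[status_col] == "case"]
    controls = cohort[cohort[status_col] == "control"]
    for name, grp in (("case", cases), ("control", controls)):
        if grp.empty:
            raise ValueError(f"empty {name} stratum for {stratify_by!r}")

    other = "loe" if stratify_by == "ad" else "ad"
    work = cohort.copy()
    work[f"{other}_case"] = (work[f"{other}_status"] == "case").astype(int)

    rows = []
    for var in [f"{other}_case"] + [v for v in _CATEGORICAL
                                    if v in work.columns]:
        x = work.loc[work[status_col] == "case", var].dropna().astype(int)
        y = work.loc[work[status_col] == "control", var].dropna().astype(int)
        table = np.array([[x.sum(), len(x) - x.sum()],
                          [y.sum(), len(y) - y.sum()]])
        if table[:, 0].sum() in (0, table.sum()):
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table)[1])
        rows.append({
            "variable": var, "type": "categorical",
            "cases_n": int(x.sum()), "cases_total": len(x),
            "cases_pct": round_percent(int(x.sum()), len(x)),
            "controls_n": int(y.sum()), "controls_total": len(y),
            "controls_pct": round_percent(int(y.sum()), len(y)),
            "p_value": p, "test": "chi2",
        })
    for var in [v for v in _CONTINUOUS if v in work.columns]:
        x = work.loc[work[status_col] == "case", var].dropna()
        y = work.loc[work[status_col] == "control", var].dropna()
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided")[1])
        rows.append({
            "variable": var, "type": "continuous",
            "cases_mean": float(x.mean()), "cases_sd": float(x.std()),
            "controls_mean": float(y.mean()), "controls_sd": float(y.std()),
            "p_value": p, "test": "wilcoxon_rank_sum",
        })
    return pd.DataFrame(rows)
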