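"""Phecode mapping, case/control rules, cohort filters and summaries."""

import numpy as np
import pandas as pd
import pytest

from adloe import phenotyping as ph


def _enc(rows):
    return pd.DataFrame(rows, columns=["patient_id", "age", "icd10"])


@pytest.fixture()
def pmap():
    return ph.PhecodeMap.default()


class TestIcdMapping:
    def test_mapped_code_yields_event(self):
        fixture = ph.PhecodeMap(entries=pd.DataFrame(
            [("G40.3", "345.11")], columns=["icd10", "phecode"]))
        events, log = ph.map_icd_to_phecodes(
            _enc([("p1", 63.0, "G40.3")]), fixture)
        assert list(events["phecode"]) == ["345.11"]
        assert log == {"n_malformed": 0, "n_unmapped": 0}

    def test_empty_table_gives_empty_stream(self, pmap):
        events, _ = ph.map_icd_to_phecodes(_enc([]), pmap)
        assert events.empty

    def test_multimap_contract_one_row_per_match(self):
        fixture = ph.PhecodeMap(entries=pd.DataFrame(
            [("G40.3", "345.11"), ("G40.3", "345.1")],
            columns=["icd10", "phecode"]))
        events, _ = ph.map_icd_to_phecodes(
            _enc([("p1", 63.0, "G40.3")]), fixture)
        assert sorted(events["phecode"]) == ["345.1", "345.11"]

    def test_malformed_and_unmapped_counted(self, pmap):
        events, log = ph.map_icd_to_phecodes(
            _enc([("p1", 63.0, "not-an-icd"), ("p1", 64.0, "Z99.89"),
                  ("p1", 65.0, "G30.9")]), pmap)
        assert log["n_malformed"] == 1
        assert log["n_unmapped"] == 1
        assert len(events) == 1


class TestLoeStatus:
    def _status(self, rows, pmap):
        enc = _enc(rows)
        events, _ = ph.map_icd_to_phecodes(enc, pmap)
        return ph.define_loe_status(events, enc, pmap)

    def test_onset_after_60_with_prior_encounter_is_case(self, pmap):
        s = self._status([("p1", 52.0, "Z00.00"), ("p1", 63.0, "G40.909")],
                         pmap)
        assert s["p1"] == "case"

    def test_onset_at_55_is_excluded_not_control(self, pmap):
        s = self._status([("p1", 50.0, "Z00.00"), ("p1", 55.0, "G40.909")],
                         pmap)
        assert s["p1"] == "excluded"

    def test_no_prior_encounter_is_excluded(self, pmap):
        s = self._status([("p1", 63.0, "G40.909")], pmap)
        assert s["p1"] == "excluded"

    def test_no_seizure_codes_is_control(self, pmap):
        s = self._status([("p1", 65.0, "Z00.00")], pmap)
        assert s["p1"] == "control"

    def test_exclude_range_code_flips_control_to_excluded(self, pmap):
        # R56.9 maps to 345.3 which sits inside the 345 exclude range
        s = self._status([("p1", 50.0, "Z00.00"), ("p1", 55.0, "R56.9")],
                         pmap)
        assert s["p1"] == "excluded"


class TestAdStatus:
    def _status(self, rows, pmap):
        enc = _enc(rows)
        events, _ = ph.map_icd_to_phecodes(enc, pmap)
        return ph.define_ad_status(events, enc, pmap)

    def test_single_ad_code_is_case(self, pmap):
        assert self._status([("p1", 70.0, "G30.9")], pmap)["p1"] == "case"

    def test_vascular_dementia_only_is_excluded(self, pmap):
        assert self._status([("p1", 70.0, "F01.50")],
                            pmap)["p1"] == "excluded"

    def test_no_dementia_codes_is_control(self, pmap):
        assert self._status([("p1", 70.0, "I10")], pmap)["p1"] == "control"

    def test_statuses_partition_patients(self, pmap):
        enc = _enc([("p1", 70.0, "G30.9"), ("p2", 70.0, "F01.50"),
                    ("p3", 70.0, "Z00.00")])
        events, _ = ph.map_icd_to_phecodes(enc, pmap)
        s = ph.define_ad_status(events, enc, pmap)
        assert set(s.index) == {"p1", "p2", "p3"}
        assert set(s) <= {"case", "control", "excluded"}


def _cohort_row(**kw):
    base = dict(patient_id="p1", sex=1, age_first_visit=58.0,
                age_last_visit=75.0, record_length=17.0,
                n_encounters_after_60=4, ad_status="control",
                loe_status="control")
    base.update(kw)
    return base


class TestFilters:
    def test_young_control_dropped_only_in_modeling_mode(self):
        cohort = pd.DataFrame([_cohort_row(age_last_visit=68.0,
                                           record_length=10.0)])
        assert len(ph.apply_cohort_filters(cohort, "full")) == 1
        assert len(ph.apply_cohort_filters(cohort, "modeling")) == 0

    def test_case_exempt_from_strict_control_rule(self):
        cohort = pd.DataFrame([_cohort_row(age_last_visit=68.0,
                                           ad_status="case")])
        assert len(ph.apply_cohort_filters(cohort, "modeling")) == 1

    def test_single_post60_encounter_dropped_in_both_modes(self):
        cohort = pd.DataFrame([_cohort_row(n_encounters_after_60=1)])
        assert ph.apply_cohort_filters(cohort, "full").empty
        assert ph.apply_cohort_filters(cohort, "modeling").empty

    def test_age_cap_at_90(self):
        cohort = pd.DataFrame([_cohort_row(age_last_visit=93.0)])
        assert ph.apply_cohort_filters(cohort, "full").empty

    def test_excluded_status_dropped_in_modeling_mode(self):
        cohort = pd.DataFrame([_cohort_row(loe_status="excluded")])
        assert len(ph.apply_cohort_filters(cohort, "full")) == 1
        assert ph.apply_cohort_filters(cohort, "modeling").empty

    def test_empty_input_empty_output(self):
        cohort = pd.DataFrame([_cohort_row()]).iloc[:0]
        assert ph.apply_cohort_filters(cohort, "full").empty

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ph.apply_cohort_filters(pd.DataFrame([_cohort_row()]), "oops")


class TestDescriptives:
    def test_percent_matches_printed_table_precision(self):
        assert ph.round_percent(571, 7351) == 7.8
        assert ph.round_percent(44, 376) == 12
        assert ph.round_percent(23, 376) == 6.1
        assert ph.round_percent(0, 100) == 0.0

    def test_table_reproduces_percentage_cells(self):
        n_case, n_ctrl, k_case, k_ctrl = 376, 1624, 44, 60
        rows = []
        for i in range(n_case):
            rows.append(_cohort_row(patient_id=f"c{i}", ad_status="case",
                                    loe_status="case" if i < k_case
                                    else "control"))
        for i in range(n_ctrl):
            rows.append(_cohort_row(patient_id=f"n{i}",
                                    loe_status="case" if i < k_ctrl
                                    else "control"))
        cohort = pd.DataFrame(rows)
        cohort["deceased"] = 0
        table = ph.descriptive_stats(cohort, "ad")
        row = table[table["variable"] == "loe_case"].iloc[0]
        assert row["cases_pct"] == 12
        assert row["cases_n"] == 44 and row["cases_total"] == 376
        assert 0 <= row["p_value"] <= 1

    def test_empty_stratum_rejected(self):
        cohort = pd.DataFrame([_cohort_row(ad_status="case")])
        with pytest.raises(ValueError, match="control"):
            ph.descriptive_stats(cohort, "ad")


class TestClosedLoop:
    def test_zero_noise_recovers_simulated_labels_exactly(self,
                                                          small_cohort):
        _, _, cohort_sim, _, enc = small_cohort
        demo = cohort_sim[["patient_id", "sex", "deceased", "death_age"]]
        cohort = ph.assemble_cohort(enc, demo)
        merged = cohort.merge(cohort_sim[["patient_id", "ad_case",
                                          "loe_case"]], on="patient_id")
        assert ((merged["ad_status"] == "case")
                == (merged["ad_case"] == 1)).all()
        assert ((merged["loe_status"] == "case")
                == (merged["loe_case"] == 1)).all()
        # controls are genuine controls, never silently excluded
        assert (merged.loc[merged["ad_case"] == 0,
                           "ad_status"] == "control").all()
        assert (merged.loc[merged["loe_case"] == 0,
                           "loe_status"] == "control").all()

    def test_comorbidity_flags_recovered(self, small_cohort):
        _, _, cohort_sim, _, enc = small_cohort
        demo = cohort_sim[["patient_id", "sex", "deceased", "death_age"]]
        cohort = ph.assemble_cohort(enc, demo)
        merged = cohort.merge(
            cohort_sim[["patient_id", "hypertension", "stroke"]],
            on="patient_id", suffixes=("", "_sim"))
        assert (merged["hypertension"]
                == merged["hypertension_sim"]).all()
        assert (merged["stroke"] == merged["stroke_sim"]).all()
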