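"""Segmentation engine: eligibility, look-back, episode merging, precedence."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import diagnoses_df, encounters_df, patients_df
from popseg import (
    SEGMENTS,
    SegmentationConfig,
    assign_segment,
    count_admissions,
    detect_conditions,
    filter_eligible,
    segment_cohort,
)
from popseg.errors import ConsistencyError


class TestEligibility:
    def test_age_and_utilization_rules(self, config):
        patients = patients_df([
            {"patient_id": "young", "birth_date": "1993-06-01"},   # age 18
            {"patient_id": "no_visit", "birth_date": "1962-01-01"},
            {"patient_id": "ok", "birth_date": "1991-01-01"},      # exactly 21
        ])
        encounters = encounters_df([
            ("young", "ED", "2012-03-01"),
            ("young", "ED", "2012-04-01"),
            ("no_visit", "specialist_clinic", "2011-12-31"),
            ("ok", "primary_care", "2012-07-01"),
        ])
        assert filter_eligible(patients, encounters, config) == {"ok"}

    def test_age_boundary_at_reference_date(self, config):
        # completed years at 1 January 2012: born 1991-01-01 -> 21 (in);
        # born 1991-01-02 -> 20 (out)
        patients = patients_df([
            {"patient_id": "on_day", "birth_date": "1991-01-01"},
            {"patient_id": "day_after", "birth_date": "1991-01-02"},
        ])
        encounters = encounters_df([
            ("on_day", "ED", "2012-03-01"),
            ("day_after", "ED", "2012-03-01"),
        ])
        assert filter_eligible(patients, encounters, config) == {"on_day"}


class TestDetectConditions:
    def test_lookback_window_boundary(self, catalog, config):
        # 5 calendar years inclusive of index year: 2008 in, 2007 out
        inside = diagnoses_df([("P1", "I10", "ICD10", "2008-01-01")])
        outside = diagnoses_df([("P1", "I10", "ICD10", "2007-12-31")])
        assert detect_conditions(inside, catalog, config) == {"hypertension"}
        assert detect_conditions(outside, catalog, config) == set()

    def test_set_semantics_over_repeats(self, catalog, config):
        dx = diagnoses_df([
            ("P1", "I10", "ICD10", "2010-01-01"),
            ("P1", "401", "ICD9", "2011-05-01"),
            ("P1", "E78.5", "ICD10", "2012-02-01"),
        ])
        assert detect_conditions(dx, catalog, config) == {
            "hypertension", "hyperlipidemia"}

    def test_rejects_multiple_patients(self, catalog, config):
        dx = diagnoses_df([
            ("P1", "I10", "ICD10", "2010-01-01"),
            ("P2", "I10", "ICD10", "2010-01-01"),
        ])
        with pytest.raises(ConsistencyError):
            detect_conditions(dx, catalog, config)


class TestCountAdmissions:
    def test_disjoint_episodes(self):
        enc = encounters_df([
            ("P1", "inpatient", "2012-01-05", "2012-01-08"),
            ("P1", "inpatient", "2012-05-01", "2012-05-02"),
            ("P1", "inpatient", "2012-09-10", "2012-09-15"),
        ])
        assert count_admissions(enc, 2012) == 3

    def test_overlapping_records_merge(self):
        enc = encounters_df([
            ("P1", "inpatient", "2012-01-05", "2012-01-10"),
            ("P1", "inpatient", "2012-01-08", "2012-01-12"),
        ])
        assert count_admissions(enc, 2012) == 1

    def test_abutting_records_merge(self):
        # next start one day after previous discharge counts as a transfer
        enc = encounters_df([
            ("P1", "inpatient", "2012-01-05", "2012-01-10"),
            ("P1", "inpatient", "2012-01-11", "2012-01-12"),
        ])
        assert count_admissions(enc, 2012) == 1

    def test_two_day_gap_does_not_merge(self):
        enc = encounters_df([
            ("P1", "inpatient", "2012-01-05", "2012-01-10"),
            ("P1", "inpatient", "2012-01-12", "2012-01-13"),
        ])
        assert count_admissions(enc, 2012) == 2

    def test_non_inpatient_never_counts(self):
        enc = encounters_df([("P1", "ED", f"2012-0{m}-01") for m in range(1, 5)])
        assert count_admissions(enc, 2012) == 0

    def test_episode_attributed_to_start_year(self):
        enc = encounters_df([
            ("P1", "inpatient", "2011-12-28", "2012-01-03"),
        ])
        assert count_admissions(enc, 2012) == 0
        assert count_admissions(enc, 2011) == 1

    def test_missing_end_date_treated_as_same_day(self):
        enc = encounters_df([
            ("P1", "inpatient", "2012-01-05"),
            ("P1", "inpatient", "2012-01-06"),
        ])
        assert count_admissions(enc, 2012) == 1


class TestAssignSegment:
    @pytest.mark.parametrize("conditions,admissions,expected,rule", [
        ({"metastatic_disease"}, 1, "end_of_life", "terminal_condition"),
        ({"atrial_fibrillation", "hypertension"}, 4, "complex_freq",
         "complex_and_frequent_admissions"),
        ({"atrial_fibrillation", "hypertension"}, 2, "complex_no_freq",
         "complex_condition"),
        (set(), 1, "serious_acute", "index_year_admission"),
        ({"hypertension", "hyperlipidemia"}, 0, "stable_chronic",
         "stable_condition"),
        (set(), 0, "mostly_healthy", "no_rule_matched"),
    ])
    def test_precedence_rules(self, catalog, config, conditions, admissions,
                              expected, rule):
        segment, fired = assign_segment(conditions, catalog, admissions, config)
        assert (segment, fired) == (expected, rule)

    def test_threshold_sharpness(self, catalog):
        cfg = SegmentationConfig(frequent_admission_threshold=3)
        below, _ = assign_segment({"atrial_fibrillation"}, catalog, 2, cfg)
        at, _ = assign_segment({"atrial_fibrillation"}, catalog, 3, cfg)
        assert (below, at) == ("complex_no_freq", "complex_freq")

    def test_terminal_flag_forces_end_of_life(self, catalog, config):
        segment, _ = assign_segment(set(), catalog, 0, config, terminal_flag=True)
        assert segment == "end_of_life"

    def test_unknown_condition_rejected(self, catalog, config):
        with pytest.raises(ConsistencyError, match="not in catalog"):
            assign_segment({"not_a_condition"}, catalog, 0, config)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        conditions=st.sets(st.sampled_from(
            ["hypertension", "asthma", "atrial_fibrillation",
             "malignancy_non_metastatic", "metastatic_disease"])),
        admissions=st.integers(min_value=0, max_value=6),
    )
    def test_admissions_never_lower_precedence(self, catalog, config,
                                               conditions, admissions):
        """Adding one admission can only move a patient toward higher precedence."""
        rank = {s: i for i, s in enumerate(config.precedence)}
        before, _ = assign_segment(conditions, catalog, admissions, config)
        after, _ = assign_segment(conditions, catalog, admissions + 1, config)
        assert rank[after] <= rank[before]


class TestSegmentCohort:
    def _five_patient_cohort(self):
        patients = patients_df([{"patient_id": f"P{i}"} for i in range(1, 6)])
        diagnoses = diagnoses_df([
            ("P1", "C78", "ICD10", "2011-06-01"),
            ("P2", "I48", "ICD10", "2011-06-01"),
            ("P2", "I10", "ICD10", "2011-06-01"),
            ("P3", "I48", "ICD10", "2011-06-01"),
            ("P5", "I10", "ICD10", "2011-06-01"),
            ("P5", "E78", "ICD10", "2011-06-01"),
        ])
        rows = [("P1", "inpatient", "2012-02-01", "2012-02-03")]
        for m in (2, 4, 6, 8):  # four disjoint admissions for P2
            rows.append(("P2", "inpatient", f"2012-0{m}-01", f"2012-0{m}-03"))
        rows += [
            ("P3", "inpatient", "2012-02-01", "2012-02-03"),
            ("P4", "inpatient", "2012-02-01", "2012-02-03"),
            ("P5", "primary_care", "2012-03-01"),
        ]
        return patients, diagnoses, encounters_df(rows)

    def test_composition_matches_single_patient_rules(self, catalog, config):
        patients, diagnoses, encounters = self._five_patient_cohort()
        out = segment_cohort(patients, diagnoses, encounters, catalog, config)
        by_id = out.set_index("patient_id")["segment"]
        assert by_id.to_dict() == {
            "P1": "end_of_life",
            "P2": "complex_freq",
            "P3": "complex_no_freq",
            "P4": "serious_acute",
            "P5": "stable_chronic",
        }

    def test_partition_property(self, catalog, config):
        patients, diagnoses, encounters = self._five_patient_cohort()
        out = segment_cohort(patients, diagnoses, encounters, catalog, config)
        assert len(out) == out["patient_id"].nunique()
        assert out["segment"].value_counts().sum() == len(out)
        assert set(out["segment"]) <= set(SEGMENTS)

    def test_assignment_carries_evidence(self, catalog, config):
        patients, diagnoses, encounters = self._five_patient_cohort()
        out = segment_cohort(patients, diagnoses, encounters, catalog,
                             config).set_index("patient_id")
        assert out.loc["P2", "index_year_admissions"] == 4
        assert out.loc["P2", "conditions_found"] == (
            "atrial_fibrillation", "hypertension")
        assert out.loc["P2", "n_conditions"] == 2

    def test_empty_cohort(self, catalog, config):
        # only patient is under-age, so nobody is eligible
        patients = patients_df([{"patient_id": "P1", "birth_date": "2000-06-01"}])
        encounters = encounters_df([("P1", "ED", "2012-01-01")])
        diagnoses = diagnoses_df([("P1", "I10", "ICD10", "2012-01-01")])
        out = segment_cohort(patients, diagnoses, encounters, catalog, config)
        assert out.empty

    def test_terminal_flag_column_respected(self, catalog, config):
        patients = patients_df([{"patient_id": "P1"}])
        patients["terminal_flag"] = True
        encounters = encounters_df([("P1", "ED", "2012-01-01")])
        dx = diagnoses_df([("P1", "I10", "ICD10", "2011-01-01")])
        out = segment_cohort(patients, dx, encounters, catalog, config)
        assert out["segment"].tolist() == ["end_of_life"]


def test_precedence_must_be_permutation():
    with pytest.raises(Exception, match="permutation"):
        SegmentationConfig(precedence=("end_of_life",) * 6)


def test_lookback_window_shrinks_with_config(catalog):
    cfg = SegmentationConfig(index_year=2012, lookback_years=1)
    dx = diagnoses_df([("P1", "I10", "ICD10", "2011-06-01")])
    assert detect_conditions(dx, catalog, cfg) == set()
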