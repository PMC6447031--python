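"""Sepsis phenotyper: organ criteria, explicit codes, windows, baselines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldlsepsis import classify_sepsis
from ldlsepsis.sepsis import (
    SepsisPhenotyper,
    compute_baselines,
    hematologic_failure,
    hepatic_failure,
    renal_failure,
)

ADMIT = "2005-06-01"


def _episode_row():
    return pd.Series(
        {
            "patient_id": "p1",
            "admit_date": pd.Timestamp(ADMIT),
            "discharge_date": pd.Timestamp("2005-06-08"),
            "icu_flag": False,
            "died_in_hospital": False,
        }
    )


def _bundle(bundle_factory, labs=None, meds=None, codes=None, icu=False,
            died=False):
    return bundle_factory(
        patients=[{"patient_id": "p1"}],
        admissions=[{"patient_id": "p1", "admit_date": ADMIT,
                     "discharge_date": "2005-06-08", "icu_flag": icu,
                     "died_in_hospital": died}],
        labs=labs or [],
        med_events=meds or [],
        coded_events=codes or [],
    )


def _episode(icu=False, died=False):
    row = _episode_row()
    row["icu_flag"] = icu
    row["died_in_hospital"] = died
    return row


class TestOrganCriterionFunctions:
    def test_renal_doubling_inclusive(self):
        assert renal_failure([1.6], 0.8) is True
        assert renal_failure([1.59], 0.8) is False
        assert renal_failure([], 0.8) is False
        assert renal_failure([1.6], None) is False

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=100, deadline=None)
    def test_renal_is_scale_invariant(self, base, window, k):
        """Rescaling all creatinine values by k > 0 never changes the call."""
        from hypothesis import assume

        assume(abs(window - 2.0 * base) > 1e-6 * base)  # off the exact boundary
        assert renal_failure([window], base) == renal_failure(
            [window * k], base * k
        )

    def test_hepatic_requires_absolute_and_relative(self):
        assert hepatic_failure([2.4], 0.6) is True       # >= 2.0 and >= 1.2
        assert hepatic_failure([1.9], 0.6) is False      # below absolute 2.0
        assert hepatic_failure([2.5], 1.5) is False      # 2.5 < 2 x 1.5
        assert hepatic_failure([2.5], None) is False

    def test_hematologic_rules(self):
        assert hematologic_failure([95.0], 210.0) is True
        assert hematologic_failure([40.0], 90.0) is False   # baseline < 100
        assert hematologic_failure([99.0], 150.0) is False  # decline only 34%
        assert hematologic_failure([50.0], None) is False

    def test_hematologic_boundaries(self):
        # 50% decline is inclusive; the low cut is strict
        assert hematologic_failure([100.0], 210.0) is False  # not < 100
        assert hematologic_failure([99.9], 199.8), "exactly 50% decline"


class TestBaselines:
    def test_lowest_creatinine_over_span(self, bundle_factory):
        bundle = _bundle(bundle_factory, labs=[
            {"patient_id": "p1", "date": "2004-11-13", "analyte": "creatinine",
             "value": 0.9},
            {"patient_id": "p1", "date": ADMIT, "analyte": "creatinine",
             "value": 1.8, "inpatient": True},
        ])
        b = compute_baselines(bundle, _episode())
        assert b.creatinine_baseline == 0.9

    def test_highest_platelets_over_span(self, bundle_factory):
        bundle = _bundle(bundle_factory, labs=[
            {"patient_id": "p1", "date": "2005-05-02", "analyte": "platelets",
             "value": 250.0},
            {"patient_id": "p1", "date": "2005-06-02", "analyte": "platelets",
             "value": 95.0, "inpatient": True},
        ])
        b = compute_baselines(bundle, _episode())
        assert b.platelet_baseline == 250.0

    def test_absent_analyte_gives_no_baseline(self, bundle_factory):
        bundle = _bundle(bundle_factory)
        b = compute_baselines(bundle, _episode())
        assert b.bilirubin_baseline is None

    def test_values_outside_span_ignored(self, bundle_factory):
        bundle = _bundle(bundle_factory, labs=[
            {"patient_id": "p1", "date": "2003-01-01", "analyte": "creatinine",
             "value": 0.5},  # > 1 year before admission
            {"patient_id": "p1", "date": "2005-05-01", "analyte": "creatinine",
             "value": 1.0},
        ])
        b = compute_baselines(bundle, _episode())
        assert b.creatinine_baseline == 1.0


class TestClassify:
    def test_norepinephrine_alone_is_cardiovascular(self, bundle_factory, config):
        bundle = _bundle(bundle_factory, meds=[
            {"patient_id": "p1", "date": ADMIT, "drug": "norepinephrine"}
        ])
        call = classify_sepsis(bundle, _episode(), config)
        assert call.cardiovascular and call.sepsis

    def test_dobutamine_needs_admin_code(self, bundle_factory, config):
        bundle = _bundle(bundle_factory, meds=[
            {"patient_id": "p1", "date": ADMIT, "drug": "dobutamine"}
        ])
        assert not classify_sepsis(bundle, _episode(), config).cardiovascular
        bundle = _bundle(
            bundle_factory,
            meds=[{"patient_id": "p1", "date": "2005-06-02", "drug": "dopamine"}],
            codes=[{"patient_id": "p1", "date": "2005-06-02", "system": "PROC",
                    "code": "00.17"}],
        )
        assert classify_sepsis(bundle, _episode(), config).cardiovascular

    def test_respiratory_needs_icu_and_ventilation(self, bundle_factory, config):
        vent = [{"patient_id": "p1", "date": ADMIT, "system": "PROC",
                 "code": "96.70"}]
        bundle = _bundle(bundle_factory, codes=vent, icu=True)
        assert classify_sepsis(bundle, _episode(icu=True), config).respiratory
        bundle = _bundle(bundle_factory, codes=vent, icu=False)
        assert not classify_sepsis(bundle, _episode(), config).respiratory
        bundle = _bundle(bundle_factory, icu=True)
        assert not classify_sepsis(bundle, _episode(icu=True), config).respiratory

    def test_explicit_code_with_normal_labs(self, bundle_factory, config):
        bundle = _bundle(
            bundle_factory,
            codes=[{"patient_id": "p1", "date": ADMIT, "system": "ICD10",
                    "code": "R65.21"}],
            labs=[{"patient_id": "p1", "date": ADMIT, "analyte": "creatinine",
                   "value": 0.9, "inpatient": True}],
        )
        call = classify_sepsis(bundle, _episode(), config)
        assert call.explicit_code and call.sepsis
        assert not any([call.renal, call.hepatic, call.hematologic,
                        call.cardiovascular, call.respiratory])

    def test_renal_flag_from_labs(self, bundle_factory, config):
        bundle = _bundle(bundle_factory, labs=[
            {"patient_id": "p1", "date": "2004-11-13", "analyte": "creatinine",
             "value": 0.9},
            {"patient_id": "p1", "date": "2005-06-02", "analyte": "creatinine",
             "value": 1.8, "inpatient": True},
        ])
        call = classify_sepsis(bundle, _episode(), config)
        assert call.renal and call.sepsis and call.evidence

    def test_no_evidence_no_sepsis(self, bundle_factory, config):
        bundle = _bundle(bundle_factory)
        call = classify_sepsis(bundle, _episode(), config)
        assert not call.sepsis and call.evidence == []

    def test_window_locality(self, bundle_factory, config):
        """Qualifying events outside days -1..+1 never set organ flags."""
        bundle = _bundle(
            bundle_factory,
            meds=[{"patient_id": "p1", "date": "2005-06-04", "drug":
                   "norepinephrine"}],  # day +3
            codes=[{"patient_id": "p1", "date": "2005-05-28", "system":
                    "ICD9CM", "code": "995.92"}],  # day -4
        )
        call = classify_sepsis(bundle, _episode(), config)
        assert not call.sepsis

    def test_adding_evidence_never_unsets_sepsis(self, bundle_factory, config):
        """Disjunction monotonicity over the six pathways."""
        bundle = _bundle(bundle_factory, meds=[
            {"patient_id": "p1", "date": ADMIT, "drug": "norepinephrine"}
        ])
        call1 = classify_sepsis(bundle, _episode(), config)
        bundle2 = _bundle(
            bundle_factory,
            meds=[{"patient_id": "p1", "date": ADMIT, "drug": "norepinephrine"}],
            codes=[{"patient_id": "p1", "date": ADMIT, "system": "ICD9CM",
                    "code": "995.92"}],
        )
        call2 = classify_sepsis(bundle2, _episode(), config)
        assert call1.sepsis and call2.sepsis
        assert call2.explicit_code

    def test_outcomes_copied_from_admission(self, bundle_factory, config):
        bundle = _bundle(bundle_factory, icu=True, died=True)
        call = classify_sepsis(bundle, _episode(icu=True, died=True), config)
        assert call.icu_admission and call.in_hospital_death
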