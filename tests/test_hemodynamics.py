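"""Unit tests for the Pmca model and derived oxygen-transport variables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemocoherence.hemodynamics import (
    A_VENOUS,
    B_ARTERIAL,
    DerivedHemodynamics,
    HemodynamicsError,
    PatientRecord,
    RecordValidationError,
    compute_c_coefficient,
    compute_do2_vo2,
    compute_o2er,
    compute_pg_vr,
    compute_pmca,
    compute_r_vr,
    derive,
    read_patient_records,
)


def _record(**over):
    base = dict(
        patient_id="P1", age=40, height=175, weight=75, heart_rate=68,
        sap=120, dap=71, map=88.1, cvp=7.1, co=4.8, sao2=100, scvo2=74.2,
        pao2=92.5, hb=14.1,
    )
    base.update(over)
    return PatientRecord(**base)


class TestCCoefficient:
    def test_reference_subject(self):
        # closed-form desk evaluation for a 40 y / 175 cm / 75 kg subject
        assert compute_c_coefficient(40, 175, 75) == pytest.approx(0.5812, abs=1e-3)

    def test_age_15_exponent_vanishes(self):
        h, w = 168.0, 62.0
        expected = 0.038 * (94.17 + 0.193 * 15) / (
            4.5 * 0.007184 * h**0.725 * w**0.425
        )
        assert compute_c_coefficient(15, h, w) == pytest.approx(expected, rel=1e-12)

    def test_increases_with_age(self):
        assert compute_c_coefficient(60, 175, 75) > compute_c_coefficient(40, 175, 75)

    @pytest.mark.parametrize("bad", [dict(age=0), dict(height=-1), dict(weight=0)])
    def test_nonpositive_inputs_name_the_field(self, bad):
        kwargs = dict(age=40, height=175, weight=75)
        kwargs.update(bad)
        with pytest.raises(HemodynamicsError, match=next(iter(bad))):
            compute_c_coefficient(**kwargs)


class TestPmca:
    def test_compliance_weights(self):
        assert A_VENOUS == 0.96
        assert B_ARTERIAL == 0.04
        assert A_VENOUS + B_ARTERIAL == 1.0

    def test_cohort_mean_inputs_give_cohort_mean_pmca(self):
        c = compute_c_coefficient(40, 175, 75)
        pmca = compute_pmca(7.1, 88.1, 4.8, c)
        assert pmca == pytest.approx(13.13, abs=0.01)

    def test_zero_flow_equal_pressures_collapses(self):
        assert compute_pmca(10, 10, 0, 0.9) == pytest.approx(10.0)

    def test_only_arterial_term(self):
        assert compute_pmca(0, 100, 0, 0) == pytest.approx(4.0)

    def test_negative_flow_rejected(self):
        with pytest.raises(HemodynamicsError):
            compute_pmca(7, 88, -1, 0.5)
        with pytest.raises(HemodynamicsError):
            compute_pmca(7, 88, 4.8, -0.1)

    @given(
        cvp=st.floats(0, 20), map_=st.floats(50, 130), co=st.floats(0, 10),
        delta=st.floats(-5, 5),
    )
    def test_affine_in_cvp(self, cvp, map_, co, delta):
        c = 0.58
        lhs = compute_pmca(cvp + delta, map_, co, c) - compute_pmca(cvp, map_, co, c)
        assert lhs == pytest.approx(A_VENOUS * delta, abs=1e-9)


class TestVenousReturn:
    def test_pg_vr_values(self):
        assert compute_pg_vr(13.1, 7.1) == pytest.approx(6.0)
        assert compute_pg_vr(14.0, 14.0) == 0.0
        assert compute_pg_vr(13.13, 7.1) == pytest.approx(6.03)

    def test_r_vr_cohort_value(self):
        assert compute_r_vr(13.13, 7.1, 4.8) == pytest.approx(1.256, abs=0.01)

    def test_r_vr_zero_gradient(self):
        assert compute_r_vr(9.0, 9.0, 4.0) == 0.0

    def test_r_vr_halves_when_co_doubles(self):
        assert compute_r_vr(13, 7, 8.0) == pytest.approx(compute_r_vr(13, 7, 4.0) / 2)

    def test_r_vr_requires_flow(self):
        with pytest.raises(HemodynamicsError):
            compute_r_vr(13, 7, 0.0)


class TestOxygenTransport:
    def test_o2er_cohort_value(self):
        assert compute_o2er(100, 74.2) == pytest.approx(0.258)

    def test_o2er_limits(self):
        assert compute_o2er(85, 85) == 0.0
        assert compute_o2er(100, 0) == 1.0

    def test_o2er_rejects_venous_above_arterial(self):
        with pytest.raises(HemodynamicsError):
            compute_o2er(90, 95)

    def test_fick_values_for_cohort_means(self):
        do2, vo2 = compute_do2_vo2(4.8, 14.1, 100, 74.2, 92.5)
        # per-subject values at cohort-mean inputs; cohort-mean DO2/VO2 are
        # means of per-subject values and differ (Jensen) - see docs
        assert do2 == pytest.approx(920, rel=0.01)
        assert vo2 == pytest.approx(234, rel=0.01)
        assert vo2 <= do2

    def test_vo2_zero_without_extraction(self):
        _, vo2 = compute_do2_vo2(5, 14, 90, 90, 90)
        assert vo2 == 0.0

    def test_do2_linear_in_co(self):
        do2_1, _ = compute_do2_vo2(2.0, 14, 99, 70, 90)
        do2_2, _ = compute_do2_vo2(4.0, 14, 99, 70, 90)
        assert do2_2 == pytest.approx(2 * do2_1, rel=1e-12)

    def test_o2er_equals_vo2_over_do2_without_dissolved_term(self):
        do2, vo2 = compute_do2_vo2(4.8, 14.1, 100, 74.2, 0.0)
        assert vo2 / do2 == pytest.approx(compute_o2er(100, 74.2), rel=1e-12)


class TestRecordsAndDerivation:
    def test_derive_is_internally_consistent(self):
        d = derive(_record())
        assert isinstance(d, DerivedHemodynamics)
        assert d.pg_vr == d.pmca - 7.1
        assert d.r_vr == d.pg_vr / 4.8
        assert 0 <= d.o2er <= 1
        assert d.pmca >= A_VENOUS * 7.1
        assert not d.nonpositive_gradient

    def test_validation_collects_all_violations(self):
        bad = _record(age=-1, co=0, scvo2=150)
        with pytest.raises(RecordValidationError) as err:
            bad.validate()
        assert len(err.value.violations) == 3

    def test_csv_round_trip(self, tmp_path):
        records = [_record(), _record(patient_id="P2", cvp=6.0, co=5.5)]
        df = pd.DataFrame([r.__dict__ for r in records])
        path = tmp_path / "patients.csv"
        df.to_csv(path, index=False)
        back = read_patient_records(path)
        assert [r.patient_id for r in back] == ["P1", "P2"]
        assert back[1].co == 5.5
        assert derive(back[0]).pmca == pytest.approx(derive(records[0]).pmca)
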