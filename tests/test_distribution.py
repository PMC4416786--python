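"""Partition-coefficient arithmetic: Kp, Veff, residual-blood correction, Kp,uu."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainpk.distribution import (
    ConcentrationRecord,
    Genotype,
    VascularParams,
    analyze_animal,
    compute_kp,
    compute_kpuu,
    correct_residual_blood,
    effective_plasma_space,
)
from brainpk.exceptions import InvalidInputError

PARAMS = VascularParams(v_water=0.0103, v_protein=0.0080)


class TestComputeKp:
    @pytest.mark.parametrize(
        "c_brain,c_plasma,expected",
        [(100.0, 100.0, 1.0), (0.0, 50.0, 0.0), (30.0, 60.0, 0.5)],
    )
    def test_ratio(self, c_brain, c_plasma, expected):
        assert compute_kp(c_brain, c_plasma) == pytest.approx(expected)

    def test_zero_plasma_names_the_animal(self):
        with pytest.raises(InvalidInputError, match="m42"):
            compute_kp(10.0, 0.0, animal_id="m42")

    def test_negative_brain_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_kp(-1.0, 10.0)


class TestEffectivePlasmaSpace:
    def test_fully_unbound_is_water_space(self):
        assert effective_plasma_space(1.0, PARAMS) == PARAMS.v_water

    def test_fully_bound_is_protein_space(self):
        assert effective_plasma_space(0.0, PARAMS) == PARAMS.v_protein

    def test_hand_arithmetic_midpoint(self):
        p = VascularParams(v_water=0.010, v_protein=0.008)
        assert effective_plasma_space(0.5, p) == pytest.approx(0.009)

    @pytest.mark.parametrize("fu", [-0.1, 1.5])
    def test_fraction_out_of_range(self, fu):
        with pytest.raises(InvalidInputError):
            effective_plasma_space(fu, PARAMS)

    @given(st.floats(0, 1), st.floats(0, 0.99), st.floats(0, 0.99))
    @settings(max_examples=200, derandomize=True)
    def test_convex_combination(self, fu, vw, vp):
        p = VascularParams(vw, vp)
        v_eff = effective_plasma_space(fu, p)
        assert min(vw, vp) - 1e-15 <= v_eff <= max(vw, vp) + 1e-15


class TestResidualBloodCorrection:
    def test_no_blood_contribution(self):
        res = correct_residual_blood(100.0, 0.0, 0.5, PARAMS)
        assert res.a_brain == pytest.approx(100.0 / (1 - PARAMS.v_water))
        assert not res.clamped

    def test_all_signal_is_residual_blood(self):
        v_eff = effective_plasma_space(0.5, PARAMS)
        res = correct_residual_blood(v_eff * 200.0, 200.0, 0.5, PARAMS)
        assert res.a_brain == pytest.approx(0.0, abs=1e-12)

    def test_negative_numerator_clamped_and_flagged(self):
        res = correct_residual_blood(0.1, 1000.0, 0.5, PARAMS)
        assert res.a_brain == 0.0
        assert res.clamped

    @given(
        st.floats(0, 1e4),
        st.floats(0, 1e4),
        st.floats(0, 1),
        st.floats(0, 0.05),
        st.floats(0, 0.05),
    )
    @settings(max_examples=300, derandomize=True)
    def test_forward_model_roundtrip(self, a_true, c_plasma, fu, vw, vp):
        """Inverting C = A*(1-Vw) + Veff*Cp recovers A up to float roundoff."""
        p = VascularParams(vw, vp)
        v_eff = effective_plasma_space(fu, p)
        c_brain_h = a_true * (1 - vw) + v_eff * c_plasma
        res = correct_residual_blood(c_brain_h, c_plasma, fu, p)
        assert res.a_brain == pytest.approx(a_true, rel=1e-12, abs=1e-10)


class TestComputeKpuu:
    def test_digoxin_wild_type_cell(self):
        assert round(compute_kpuu(0.05, 44.8, 0.594), 3) == 0.002

    def test_verapamil_humanized_cell(self):
        assert round(compute_kpuu(9.0, 48.2, 0.117), 2) == 1.60

    def test_unity_by_construction(self):
        assert compute_kpuu(44.8 * 0.594, 44.8, 0.594) == pytest.approx(1.0)

    @pytest.mark.parametrize("vu,fu", [(0.0, 0.5), (44.8, 0.0), (-1.0, 0.5)])
    def test_nonpositive_inputs_rejected(self, vu, fu):
        with pytest.raises(InvalidInputError):
            compute_kpuu(1.0, vu, fu)

    @given(
        st.floats(1e-6, 1e3),
        st.floats(1e-3, 1e3),
        st.floats(1e-3, 1.0),
        st.floats(0.1, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, c_brain, c_plasma, fu, k):
        """Multiplying every concentration by k leaves Kp and Kp,uu unchanged."""
        kp1 = compute_kp(c_brain, c_plasma)
        kp2 = compute_kp(k * c_brain, k * c_plasma)
        assert kp2 == pytest.approx(kp1, rel=1e-9)
        assert compute_kpuu(kp2, 44.8, fu) == pytest.approx(
            compute_kpuu(kp1, 44.8, fu), rel=1e-9
        )


class TestAnalyzeAnimal:
    def test_zero_noise_forward_model_recovers_truth(self):
        """An animal generated with known Kp,uu yields that Kp,uu exactly."""
        kpuu_true, vu, fu, c_plasma = 0.6 / (48.2 * 0.115), 48.2, 0.115, 100.0
        v_eff = effective_plasma_space(fu, PARAMS)
        a = kpuu_true * fu * c_plasma * vu
        c_brain_h_per_g = a * (1 - PARAMS.v_water) + v_eff * c_plasma
        rec = ConcentrationRecord(
            "a1", Genotype.C57BL6_WT, "verapamil", c_plasma, c_brain_h_per_g / 5.0, 5.0
        )
        res = analyze_animal(rec, vu, fu, PARAMS)
        assert res.kpuu == pytest.approx(kpuu_true, rel=1e-12)
        assert res.kp == pytest.approx(0.6 / 100.0 * 100.0, rel=1e-12)
        assert not res.clamped

    def test_record_invariants(self):
        with pytest.raises(InvalidInputError):
            ConcentrationRecord("a", Genotype.HMDR1, "digoxin", -1.0, 5.0, 5.0)
        with pytest.raises(InvalidInputError):
            ConcentrationRecord("a", Genotype.HMDR1, "digoxin", 1.0, 5.0, 0.5)

    def test_dilution_correction_applied(self):
        rec = ConcentrationRecord("a", Genotype.HMDR1, "digoxin", 10.0, 20.0, 5.0)
        assert rec.c_brain_per_g == pytest.approx(100.0)
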