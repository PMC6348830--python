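"""Interspecies extrapolation methods and the comparison report."""

import numpy as np
import pytest

from biokin.curves import ScalingSpec, SpeciesProfile
from biokin.reference import REFERENCE_TIACS, cohort_profile, human_reference, reference_tiacs
from biokin.tiac import TIACEstimate, tiac_value
from biokin.xscale import (
    ScalingError,
    compare,
    method1_same,
    method2_mass,
    method3_time,
    method4_combined,
    method5_allometric,
    round_factor,
)

from conftest import make_fit, random_valid_model

MOUSE = SpeciesProfile("mouse", 0.026, {"kidneys": 0.0004, "liver": 0.0014})
HUMAN = SpeciesProfile("human", 61.0, {"kidneys": 0.31, "liver": 1.8})


def est(value, region="kidneys", species="mouse", unit="h"):
    return TIACEstimate(value=value, se=0.0, region=region, species=species, unit=unit)


class TestMethod1:
    def test_identity_on_pig_kidney(self):
        t = est(7.67, species="pig")
        assert method1_same(t).value == 7.67

    def test_zero(self):
        assert method1_same(est(0.0)).value == 0.0

    def test_unit_preserved(self):
        t = est(0.0002, region="blood", species="pig", unit="h_per_ml")
        assert method1_same(t).unit == "h_per_ml"


class TestMethod2:
    def test_equal_fractions_unchanged(self):
        animal = SpeciesProfile("a", 10.0, {"kidneys": 0.05})
        human = SpeciesProfile("h", 70.0, {"kidneys": 0.35})  # same fraction 0.005
        assert method2_mass(est(2.5), animal, human, "kidneys").value == pytest.approx(2.5)

    def test_linearity_in_fraction_ratio(self):
        animal = SpeciesProfile("a", 10.0, {"kidneys": 0.05})
        human = SpeciesProfile("h", 10.0, {"kidneys": 0.10})  # double fraction
        assert method2_mass(est(2.0), animal, human, "kidneys").value == pytest.approx(4.0)

    def test_hand_computed_example(self):
        # tiac 1.44 h, animal fraction 0.016, human fraction 0.0048 -> 0.432 h
        animal = SpeciesProfile("a", 1.0, {"kidneys": 0.016})
        human = SpeciesProfile("h", 1.0, {"kidneys": 0.0048})
        assert method2_mass(est(1.44), animal, human, "kidneys").value == pytest.approx(0.432)

    def test_missing_organ_mass_refused(self):
        bare = SpeciesProfile("mouse", 0.026)  # e.g. blood without volume data
        with pytest.raises(ScalingError, match="mass"):
            method2_mass(est(1.44), bare, HUMAN, "kidneys")


class TestMethod3:
    def test_equal_masses_identity(self):
        fit = make_fit("bi", [5.0, 0.3, 6.7, 0.009], species="pig", region="kidneys", unit="pct_ia")
        scaled_fit, scaled = method3_time(fit, 28.0, 28.0)
        np.testing.assert_allclose(scaled_fit.params, fit.params)
        assert scaled.value == pytest.approx(tiac_value(fit.form, fit.params))

    def test_no_physical_decay_scales_tiac_by_c(self):
        # with lambda_phys = 0 the closed form is int A e^{-lam t / c} = c A/lam
        fit = make_fit("mono", [50.0, 0.05], lambda_phys=0.0, species="pig", region="kidneys")
        c = (61.0 / 28.0) ** 0.25
        _, scaled = method3_time(fit, 28.0, 61.0)
        assert scaled.value == pytest.approx(c * 0.5 / 0.05)

    def test_tiac_between_original_and_c_times_original(self):
        fit = make_fit("bi", [5.0, 0.3, 6.7, 0.009], species="pig", region="kidneys")
        original = tiac_value(fit.form, fit.params)
        c = (61.0 / 28.0) ** 0.25
        _, scaled = method3_time(fit, 28.0, 61.0)
        assert original < scaled.value < c * original

    def test_scale_physical_decay_variant_scales_everything(self):
        fit = make_fit("mono", [50.0, 0.05], species="pig", region="kidneys")
        c = (61.0 / 28.0) ** 0.25
        _, scaled = method3_time(fit, 28.0, 61.0, ScalingSpec(scale_physical_decay=True))
        assert scaled.value == pytest.approx(c * 0.5 / 0.05)

    def test_amplitudes_unchanged(self):
        fit = make_fit("bi", [5.0, 0.3, 6.7, 0.009], species="pig", region="kidneys")
        scaled_fit, _ = method3_time(fit, 28.0, 61.0)
        assert scaled_fit.params[0] == fit.params[0]
        assert scaled_fit.params[2] == fit.params[2]

    def test_positively_homogeneous_in_amplitudes(self):
        fit1 = make_fit("bi", [5.0, 0.3, 6.7, 0.009], species="pig", region="kidneys")
        fit2 = make_fit("bi", [10.0, 0.3, 13.4, 0.009], species="pig", region="kidneys")
        _, s1 = method3_time(fit1, 28.0, 61.0)
        _, s2 = method3_time(fit2, 28.0, 61.0)
        assert s2.value == pytest.approx(2.0 * s1.value)


class TestMethod4:
    def test_double_identity(self):
        fit = make_fit("bi", [5.0, 0.3, 6.7, 0.009], species="a", region="kidneys", unit="pct_ia")
        animal = SpeciesProfile("a", 28.0, {"kidneys": 0.13})
        human = SpeciesProfile("h", 28.0, {"kidneys": 0.13})
        scaled = method4_combined(fit, animal, human, "kidneys")
        assert scaled.value == pytest.approx(tiac_value(fit.form, fit.params))

    def test_c_equals_one_reduces_to_method2(self):
        fit = make_fit("bi", [5.0, 0.3, 6.7, 0.009], species="a", region="kidneys", unit="pct_ia")
        animal = SpeciesProfile("a", 28.0, {"kidneys": 0.13})
        human = SpeciesProfile("h", 28.0, {"kidneys": 0.31})
        t = est(tiac_value(fit.form, fit.params), species="a")
        assert method4_combined(fit, animal, human, "kidneys").value == pytest.approx(
            method2_mass(t, animal, human, "kidneys").value
        )

    def test_no_decay_mono_closed_form(self):
        fit = make_fit("mono", [50.0, 0.05], lambda_phys=0.0, species="a", region="kidneys")
        animal = SpeciesProfile("a", 1.0, {"kidneys": 0.01})
        human = SpeciesProfile("h", 16.0, {"kidneys": 0.32})  # fraction ratio 2
        c = 16.0**0.25
        scaled = method4_combined(fit, animal, human, "kidneys")
        assert scaled.value == pytest.approx(0.5 / 0.05 * c * 2.0)

    def test_composition_equals_sequential_calls(self, rng):
        spec = ScalingSpec()
        animal = SpeciesProfile("a", 0.026, {"kidneys": 0.0004})
        human = SpeciesProfile("h", 61.0, {"kidneys": 0.31})
        for _ in range(50):
            form, params = random_valid_model(rng)
            fit = make_fit(form, params, species="a", region="kidneys", unit="pct_ia")
            combined = method4_combined(fit, animal, human, "kidneys", spec)
            _, time_scaled = method3_time(fit, animal.m_wb, human.m_wb, spec)
            seq = method2_mass(
                est(time_scaled.value, species="a"), animal, human, "kidneys"
            )
            assert combined.value == pytest.approx(seq.value, rel=1e-12)


class TestMethod5:
    def test_mouse_liver_published_value(self):
        t = est(0.75, region="liver")
        scaled = method5_allometric(t, 0.026, 61.0, "liver")
        assert round(scaled.value, 2) == 0.40

    def test_b_equals_one_identity(self):
        spec = ScalingSpec(allometric_b={"liver": 1.0})
        t = est(0.75, region="liver")
        assert method5_allometric(t, 0.026, 61.0, "liver", spec).value == pytest.approx(0.75)

    def test_power_of_mass_ratio(self):
        spec = ScalingSpec(allometric_b={"liver": 0.75})
        t = est(2.0, region="liver")
        # mass ratio 16, b = 0.75 -> 16^(-0.25) = 0.5 exactly
        assert method5_allometric(t, 1.0, 16.0, "liver", spec).value == pytest.approx(1.0)

    def test_missing_exponent_rejected(self):
        t = est(0.0002, region="blood", species="pig", unit="h_per_ml")
        with pytest.raises(ScalingError, match="allometric"):
            method5_allometric(t, 28.0, 61.0, "blood")

    def test_linearity_in_tiac(self):
        a = method5_allometric(est(1.0, region="liver"), 0.026, 61.0, "liver").value
        b = method5_allometric(est(3.0, region="liver"), 0.026, 61.0, "liver").value
        assert b == pytest.approx(3.0 * a)


def test_all_methods_reduce_to_method1_for_equal_species(rng):
    profile = SpeciesProfile("same", 61.0, {"kidneys": 0.31})
    spec = ScalingSpec()
    for _ in range(20):
        form, params = random_valid_model(rng)
        fit = make_fit(form, params, species="same", region="kidneys", unit="pct_ia")
        t = est(tiac_value(form, params), species="same")
        base = method1_same(t).value
        assert method2_mass(t, profile, profile, "kidneys").value == pytest.approx(base)
        assert method3_time(fit, 61.0, 61.0, spec)[1].value == pytest.approx(base)
        assert method4_combined(fit, profile, profile, "kidneys", spec).value == pytest.approx(base)
        assert method5_allometric(t, 61.0, 61.0, "kidneys", spec).value == pytest.approx(base)


class TestCompare:
    def test_mouse_kidney_underestimation_factor_4(self):
        scaled = [method1_same(est(1.44, species="mouse"))]
        report = compare(scaled, [est(5.85, species="human")])
        (row,) = report.rows
        assert row["direction"] == "under"
        assert row["factor_rounded"] == 4

    def test_pig_kidney_overestimation_factor_1_3(self):
        scaled = [method1_same(est(7.67, species="pig"))]
        report = compare(scaled, [est(5.85, species="human")])
        (row,) = report.rows
        assert row["direction"] == "over"
        assert row["factor_rounded"] == pytest.approx(1.3)

    def test_equal_values_factor_one(self):
        scaled = [method1_same(est(5.85, species="pig"))]
        report = compare(scaled, [est(5.85, species="human")])
        (row,) = report.rows
        assert row["direction"] == "equal" and row["factor_rounded"] == 1.0

    def test_missing_reference_rejected(self):
        scaled = [method1_same(est(1.44, region="spleen"))]
        with pytest.raises(ScalingError, match="spleen"):
            compare(scaled, [est(5.85, region="kidneys", species="human")])

    def test_rounding_rule_boundary(self):
        assert round_factor(3.5) == 4
        assert round_factor(3.4) == 3.4
        assert round_factor(1.26) == 1.3


def test_reference_values_consistency():
    ref = {(t.species, t.region): t for t in reference_tiacs()}
    assert ref[("mouse", "kidneys")].value == 1.44
    assert ref[("pig", "blood")].unit == "h_per_ml"
    assert len(human_reference()) == 3
    assert cohort_profile("mouse").m_wb == 0.026
    assert set(REFERENCE_TIACS) == {
        (s, r) for s in ("mouse", "pig", "human") for r in ("kidneys", "liver", "blood")
    }
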