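"""Disposition model: clearance scaling, ODE solution oracles, calibration."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from chqdose import pkmodel
from chqdose.pkmodel import (
    CompoundParams,
    scale_clearance,
    scale_volume,
    simulate_profile,
)
from chqdose.population import Subject
from chqdose.regimen import DoseEvent, Regimen, Schedule


def _neonate(weight=3.5, mat=0.3):
    return Subject(
        subject_id=1, age=0.02, sex="female", weight=weight,
        f_cyp3a4=mat, f_cyp2c8=mat, f_gfr=mat,
    )


def _regimen(events):
    return Regimen(
        events=tuple(DoseEvent(t, a) for t, a in events),
        schedule_mg_per_kg=Schedule(0.0, 0.0, 0.0),
    )


class TestClearanceScaling:
    def test_adult_70kg_recovers_cl_adult_and_pathway_ratios(self, adult_70kg, params):
        cb = scale_clearance(adult_70kg, params)
        assert cb.cl_total == pytest.approx(params.cl_adult)
        fractions = np.array([cb.cl_cyp3a4, cb.cl_cyp2c8, cb.cl_renal, cb.cl_other])
        assert fractions / cb.cl_total == pytest.approx([0.15, 0.20, 0.56, 0.09])

    def test_components_sum_to_total(self, params):
        cb = scale_clearance(_neonate(), params)
        assert cb.cl_cyp3a4 + cb.cl_cyp2c8 + cb.cl_renal + cb.cl_other == pytest.approx(
            cb.cl_total
        )

    def test_neonate_uniform_maturation_closed_form(self, params):
        # all four pathways at maturation 0.3: the fm decomposition collapses
        cb = scale_clearance(_neonate(3.5, 0.3), params, other_maturation=0.3)
        expected = params.cl_adult * 0.3 * (3.5 / 70.0) ** 0.75
        assert cb.cl_total == pytest.approx(expected, rel=1e-12)


class TestVolumeScaling:
    def test_reference_split_arithmetic(self, reference_adult, params):
        v1, v2 = scale_volume(reference_adult, params)
        vss = params.vss_per_kg * 75.0
        assert v1 == pytest.approx(params.v1_fraction * vss)
        assert v1 + v2 == pytest.approx(vss)

    def test_vss_linear_in_weight(self, params):
        v1a, v2a = scale_volume(_neonate(3.0), params)
        v1b, v2b = scale_volume(_neonate(6.0), params)
        assert v1b + v2b == pytest.approx(2.0 * (v1a + v2a))


class TestSimulation:
    def test_empty_regimen_all_zero(self, reference_adult, params):
        prof = simulate_profile(
            reference_adult, params, _regimen([]), duration=48.0, grid_step=2.0
        )
        assert np.all(prof.concentrations == 0.0)

    def test_concentration_zero_at_dose_time(self, reference_adult, params):
        prof = simulate_profile(
            reference_adult, params, _regimen([(0.0, 300.0)]), 168.0, 0.5
        )
        assert prof.concentrations[0] == 0.0
        assert prof.concentrations[1:].max() > 0.0

    def test_one_compartment_closed_form_when_decoupled(self, reference_adult, params):
        """With q_inter ~ 0 the central compartment follows the textbook
        first-order-absorption solution C = F D ka / (V (ka - k)) (e^-kt - e^-ka t)."""
        p = replace(params, q_inter=1e-12)
        dose = 300.0
        prof = simulate_profile(reference_adult, p, _regimen([(0.0, dose)]), 240.0, 0.5)
        v1, _ = scale_volume(reference_adult, p)
        k = scale_clearance(reference_adult, p).cl_total / v1
        t = prof.times
        expected = (
            p.f_bioavail * dose * p.ka / (v1 * (p.ka - k))
            * (np.exp(-k * t) - np.exp(-p.ka * t))
        )
        mask = expected > expected.max() * 1e-6  # skip fully-decayed tail
        assert prof.concentrations[mask] == pytest.approx(expected[mask], rel=1e-3)

    def test_superposition_of_two_doses(self, reference_adult, params):
        both = simulate_profile(
            reference_adult, params, _regimen([(0.0, 300.0), (12.0, 300.0)]), 240.0, 2.0
        )
        single = simulate_profile(
            reference_adult, params, _regimen([(0.0, 300.0)]), 240.0, 2.0
        )
        shift = int(12.0 / 2.0)
        summed = single.concentrations.copy()
        summed[shift:] += single.concentrations[: summed.size - shift]
        nz = summed > 0
        assert both.concentrations[nz] == pytest.approx(summed[nz], rel=1e-3)

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_dose_linearity_property(self, c, params):
        adult = _neonate(weight=70.0, mat=1.0)
        base = simulate_profile(adult, params, _regimen([(0.0, 100.0)]), 120.0, 4.0)
        scaled = simulate_profile(
            adult, params, _regimen([(0.0, 100.0 * c)]), 120.0, 4.0
        )
        assert scaled.concentrations[1:] == pytest.approx(
            c * base.concentrations[1:], rel=1e-9
        )

    def test_mass_balance_at_all_times(self, reference_adult, params):
        """depot + central + peripheral + eliminated = F x administered."""
        cb = scale_clearance(reference_adult, params)
        v1, v2 = scale_volume(reference_adult, params)
        size = (75.0 / 70.0) ** 0.75
        times, conc, states = pkmodel.simulate_cohort(
            cb.cl_total, v1, v2, params.q_inter * size, params.ka, params.f_bioavail,
            np.array([0.0, 12.0]), np.array([600.0, 300.0]), 480.0, 2.0,
            return_states=True,
        )
        administered = np.where(times >= 12.0, 900.0, 600.0)
        total = states[0].sum(axis=1)
        assert total == pytest.approx(params.f_bioavail * administered, rel=1e-9)

    def test_misaligned_event_time_rejected(self, params):
        with pytest.raises(ValueError):
            pkmodel.simulate_cohort(
                10.0, 100.0, 1000.0, 50.0, 0.5, 0.8,
                np.array([3.0]), np.array([100.0]), 48.0, 2.0,
            )

    def test_negative_dose_rejected(self, params):
        with pytest.raises(ValueError):
            pkmodel.simulate_cohort(
                10.0, 100.0, 1000.0, 50.0, 0.5, 0.8,
                np.array([0.0]), np.array([-1.0]), 48.0, 2.0,
            )


class TestCalibration:
    def test_shipped_default_hits_half_life_target(self, params):
        t_half = pkmodel.terminal_half_life_days(params)
        assert t_half == pytest.approx(params.t_half_terminal_target, rel=0.05)

    def test_calibration_reaches_target_exactly(self, params):
        cal = pkmodel.calibrate_adult(replace(params, cl_adult=5.0))
        assert pkmodel.terminal_half_life_days(cal) == pytest.approx(
            params.t_half_terminal_target, rel=1e-4
        )

    def test_calibration_idempotent(self, params):
        once = pkmodel.calibrate_adult(params)
        twice = pkmodel.calibrate_adult(once)
        assert twice.cl_adult == pytest.approx(once.cl_adult, rel=1e-3)

    def test_halving_vss_roughly_halves_recovered_clearance(self, params):
        full = pkmodel.calibrate_adult(params)
        half = pkmodel.calibrate_adult(replace(params, vss_per_kg=params.vss_per_kg / 2))
        assert half.cl_adult / full.cl_adult == pytest.approx(0.5, rel=0.2)

    def test_bad_bracket_raises_with_diagnostics(self, params):
        with pytest.raises(RuntimeError, match="bracket"):
            pkmodel.calibrate_adult(params, cl_bracket=(400.0, 500.0))


class TestParameterValidation:
    def test_pathway_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CompoundParams(fm_cyp3a4=0.5)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            CompoundParams(ka=0.0)
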