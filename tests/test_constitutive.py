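"""1D material laws: bone plasticity, ligament fiber law, foam pad."""

import numpy as np
import pytest

from agelimb.constitutive import (
    BoneStressState,
    FoamPad,
    LigamentFiberLaw,
    cancellous_update,
    cortical_update,
    fiber_stress,
    foam_force,
    ligament_law_for_age,
)
from agelimb.errors import DomainError
from agelimb.materials import cancellous_params, cortical_params


@pytest.fixture
def fem30():
    return cortical_params(30, "femur")


@pytest.fixture
def canc30():
    return cancellous_params(30, "tibia")


def _ramp(update, increments):
    state = BoneStressState()
    history = []
    for d in increments:
        state = update(state, d)
        history.append(state)
    return history


class TestCorticalLaw:
    def test_elastic_branch_is_modulus_times_strain(self, fem30):
        s = cortical_update(BoneStressState(), 0.001, fem30)
        assert s.stress == pytest.approx(16.24, abs=1e-6)
        assert not s.failed and s.plastic_strain == 0.0

    def test_rate_doubles_yield_onset_at_reference_rate(self, fem30):
        # static yield strain ~0.0071; doubled (dynamic) ~0.0142:
        # at 1.2% strain the static path has yielded, the dynamic has not
        static = _ramp(lambda st, d: cortical_update(st, d, fem30, 0.0),
                       [0.001] * 12)[-1]
        dynamic = _ramp(lambda st, d: cortical_update(st, d, fem30, 360.5),
                        [0.001] * 12)[-1]
        assert static.plastic_strain > 0
        assert static.stress < 2.0 * fem30.yield_stress
        assert dynamic.plastic_strain == 0.0
        assert dynamic.stress == pytest.approx(16240 * 0.012, rel=1e-9)

    def test_failure_zeroes_stress_permanently(self, fem30):
        hist = _ramp(lambda st, d: cortical_update(st, d, fem30),
                     [0.005] * 8)
        assert hist[-1].failed and hist[-1].stress == 0.0
        # keeps zero stress on further loading
        again = cortical_update(hist[-1], 0.01, fem30)
        assert again.failed and again.stress == 0.0

    def test_unloading_slope_is_elastic_modulus_at_any_rate(self, fem30):
        loaded = _ramp(lambda st, d: cortical_update(st, d, fem30, 100.0),
                       [0.002] * 10)[-1]
        unloaded = cortical_update(loaded, -0.001, fem30, 100.0)
        dslope = (loaded.stress - unloaded.stress) / 0.001
        assert dslope == pytest.approx(16240, rel=1e-9)

    def test_closed_cycle_dissipation_nonnegative(self, fem30):
        state = BoneStressState()
        work = 0.0
        prev_stress, prev_eps = 0.0, 0.0
        for d in [0.002] * 12 + [-0.002] * 12:
            state = cortical_update(state, d, fem30)
            work += 0.5 * (state.stress + prev_stress) * (state.total_strain - prev_eps)
            prev_stress, prev_eps = state.stress, state.total_strain
        assert work >= -1e-12

    def test_non_finite_increment_rejected(self, fem30):
        with pytest.raises(DomainError):
            cortical_update(BoneStressState(), float("nan"), fem30)


class TestCancellousLaw:
    def test_elastic_then_flat_plateau(self, canc30):
        elastic = cancellous_update(BoneStressState(), 0.005, canc30)
        assert elastic.stress == pytest.approx(752.0 * 0.005, rel=1e-6)
        plastic = _ramp(lambda st, d: cancellous_update(st, d, canc30),
                        [0.01] * 10)[-1]
        assert plastic.stress == pytest.approx(canc30.yield_stress, rel=1e-9)

    def test_fails_at_13_4_percent(self, canc30):
        s = cancellous_update(BoneStressState(total_strain=0.13), 0.01, canc30)
        assert s.failed and s.stress == 0.0


class TestFiberLaw:
    def test_no_stress_at_or_below_reference(self, young_law):
        assert fiber_stress(1.0, young_law) == 0.0
        assert fiber_stress(0.8, young_law) == 0.0

    def test_branches_agree_at_transition(self, young_law):
        ls = young_law.lambda_star
        toe = young_law.C3 * (np.expm1(young_law.C4 * (ls - 1.0)))
        lin = young_law.C5 / young_law.C4 - young_law.C3
        assert toe == pytest.approx(lin, rel=1e-10)
        assert fiber_stress(ls, young_law) == pytest.approx(lin, rel=1e-10)

    def test_slope_reaches_c5_at_transition(self, young_law):
        ls = young_law.lambda_star
        h = 1e-7
        left = (fiber_stress(ls, young_law) - fiber_stress(ls - h, young_law)) / h
        assert left == pytest.approx(young_law.C5, rel=1e-4)

    def test_elderly_softer_and_ruptures_earlier(self, young_law, elderly_law):
        lams = np.linspace(1.001, 1.2, 50)
        young = fiber_stress(lams, young_law)
        old = fiber_stress(lams, elderly_law)
        assert np.all(old < young)
        assert elderly_law.failure_strain < young_law.failure_strain

    def test_rupture_zeroes_stress(self, elderly_law):
        past = 1.0 + elderly_law.failure_strain + 1e-9
        assert fiber_stress(past, elderly_law) == 0.0
        assert fiber_stress(1.5, elderly_law) == 0.0

    def test_nondecreasing_before_rupture(self, young_law):
        lams = np.linspace(1.0, 1.0 + young_law.failure_strain - 1e-6, 400)
        sig = fiber_stress(lams, young_law)
        assert np.all(np.diff(sig) >= -1e-12)

    def test_age_interpolation_clamped_linear(self):
        assert ligament_law_for_age(25) == ligament_law_for_age(30)
        assert ligament_law_for_age(80) == ligament_law_for_age(70)
        mid = ligament_law_for_age(50)
        assert mid.C5 == pytest.approx((836.42 + 695.66) / 2)

    def test_invalid_constants_rejected(self):
        with pytest.raises(DomainError):
            LigamentFiberLaw(C1=1, C3=10.0, C4=100.0, C5=500.0,
                             bulk_modulus=4.0, failure_strain=0.4)


class TestFoam:
    def test_zero_depth_zero_force(self):
        assert foam_force(0.0, FoamPad()) == 0.0

    def test_force_linear_in_footprint(self):
        pad1 = FoamPad(width=100, depth=120)
        pad2 = FoamPad(width=200, depth=120)
        assert foam_force(10.0, pad2) == pytest.approx(2 * foam_force(10.0, pad1))

    def test_monotone_in_depth(self):
        pad = FoamPad()
        depths = np.linspace(0, 49.0, 60)
        forces = [foam_force(d, pad) for d in depths]
        assert all(b >= a for a, b in zip(forces, forces[1:]))

    def test_densification_rejected(self):
        with pytest.raises(DomainError, match="densification"):
            foam_force(50.0, FoamPad())

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(DomainError):
            FoamPad(curve=((0.0, 0.0), (0.3, 1.0), (0.5, 0.5)))
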