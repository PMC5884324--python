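"""Explicit beam solver: elastic oracle, convergence, events, determinism."""

import math

import numpy as np
import pytest

from agelimb.beam import (
    FractureEvent,
    build_beam,
    build_fibers,
    detect_events,
)
from agelimb.geometry import STATIONS, CrossSection, LongBoneGeometry
from agelimb.materials import cancellous_params, cortical_params
from agelimb.rigs import (
    simulate_four_point_knee,
    simulate_three_point,
    static_center_deflection,
)


@pytest.fixture(scope="module")
def uniform_tube():
    sec = CrossSection(28.0, 14.0)
    geom = LongBoneGeometry("femur", 400.0,
                            tuple((f, sec) for f in STATIONS))
    cort = cortical_params(30, "femur")
    canc = cancellous_params(30, "femur")
    return geom, cort, canc


def test_fiber_section_reproduces_annulus_inertia(uniform_tube):
    geom, cort, canc = uniform_tube
    fibers = build_fibers([CrossSection(28.0, 14.0)], cort, canc)
    i_cort = math.pi * (28.0**4 - 14.0**4) / 64.0
    i_canc = math.pi * 14.0**4 / 64.0
    ei_exact = cort.elastic_modulus * 1000.0 * i_cort + canc.elastic_modulus * i_canc
    assert fibers.elastic_EI[0] == pytest.approx(ei_exact, rel=5e-3)


def test_quasi_static_deflection_matches_closed_form(uniform_tube):
    """Simply supported beam, center load: delta = F L^3 / (48 EI)."""
    geom, cort, canc = uniform_tube
    model = build_beam(geom, cort, canc, n_nodes=33)
    F = 500.0
    w = static_center_deflection(model, F)
    i_cort = math.pi * (28.0**4 - 14.0**4) / 64.0
    i_canc = math.pi * 14.0**4 / 64.0
    ei = cort.elastic_modulus * 1000.0 * i_cort + canc.elastic_modulus * i_canc
    exact = F * 400.0**3 / (48.0 * ei)
    assert w == pytest.approx(exact, rel=0.02)


def test_zero_speed_impactor_leaves_everything_at_rest():
    th = simulate_three_point("thigh", 70, speed=0.0, t_end=2.0)
    assert np.all(th.impactor_force == 0.0)
    assert np.all(th.impactor_displacement == 0.0)
    assert np.all(th.bending_moment == 0.0)
    assert th.events == []


def test_halved_time_step_changes_peak_force_below_one_percent():
    ref = simulate_three_point("thigh", 70)
    # the solver's stable step for this rig, then halve it
    from agelimb.beam import ExplicitSystem, SoftPad
    from agelimb.rigs import FLESH_MASS, _aged_beam

    beam = _aged_beam("femur", 70, 33, FLESH_MASS["thigh"])
    dt0 = ExplicitSystem([beam], pad=SoftPad(k=350.0, toe=15.0),
                         strike=(0, 16), impactor_speed=1.5).stable_dt()
    fine = simulate_three_point("thigh", 70, dt=dt0 / 2.0)
    p_ref = ref.impactor_force.max()
    p_fine = fine.impactor_force.max()
    assert abs(p_fine - p_ref) / p_ref < 0.01


def test_mesh_refinement_converged_on_three_point_rig():
    coarse = simulate_three_point("thigh", 70, n_nodes=33)
    fine = simulate_three_point("thigh", 70, n_nodes=65)
    p1, p2 = coarse.impactor_force.max(), fine.impactor_force.max()
    assert abs(p2 - p1) / p1 < 0.03
    t1 = coarse.first_event("femur", "cortical_fracture").time
    t2 = fine.first_event("femur", "cortical_fracture").time
    assert abs(t2 - t1) / t1 < 0.03


def test_determinism_bit_identical_reruns():
    a = simulate_three_point("calf", 70)
    b = simulate_three_point("calf", 70)
    assert np.array_equal(a.impactor_force, b.impactor_force)
    assert np.array_equal(a.bending_moment, b.bending_moment)
    assert a.events == b.events


def test_energy_balance_three_point_below_one_percent():
    th = simulate_three_point("thigh", 30)
    assert th.energy["error"].max() < 0.01


def test_soft_tissue_toe_precedes_structural_loading():
    """Force rises slowly while flesh compresses, then sharply."""
    th = simulate_three_point("thigh", 30)
    u = th.impactor_displacement
    f = th.impactor_force
    early = f[(u > 1.0) & (u < 8.0)]
    later = f[(u > 20.0) & (u < 28.0)]
    mean_early_slope = early.max() / 8.0
    mean_later_slope = (later.max() - later.min()) / 8.0
    assert mean_later_slope > 2.0 * mean_early_slope


class TestFourPointKnee:
    def test_moment_monotone_before_rupture(self):
        th = simulate_four_point_knee(70)
        rupture = th.first_event("MCL", "ligament_rupture")
        pre = th.bending_moment[th.time < rupture.time]
        assert np.all(np.diff(pre) >= -1e-9)

    def test_moment_peaks_at_rupture_then_drops(self):
        th = simulate_four_point_knee(70)
        i_peak = int(np.argmax(th.bending_moment))
        rupture = th.first_event("MCL", "ligament_rupture")
        assert th.time[i_peak] == pytest.approx(rupture.time, abs=0.2)
        assert th.bending_moment[-1] < 0.8 * th.bending_moment[i_peak]

    def test_rate_independent_curve_matches_quasi_static_oracle(self):
        """Incremental quasi-static moment-angle oracle (independent path)."""
        from agelimb.constitutive import fiber_stress
        from agelimb.materials import material_table
        from agelimb.rigs import KNEE_DEFAULTS, _mcl_bundle

        law = material_table(70).ligament
        levers, areas, gains = _mcl_bundle(law)
        th = simulate_four_point_knee(70, rate=1.0)
        th_slow = simulate_four_point_knee(70, rate=0.25)
        for angle in (3.0, 6.0, 9.0):
            theta = math.radians(angle)
            oracle = sum(
                a * fiber_stress(1.0 + g * theta, law, include_matrix=True) * l
                for a, g, l in zip(areas, gains, levers)
                if g * theta < law.failure_strain
            ) + KNEE_DEFAULTS["capsule_rotation"] * theta
            oracle /= 1000.0
            m_fast = np.interp(angle, th.knee_angle, th.bending_moment)
            m_slow = np.interp(angle, th_slow.knee_angle, th_slow.bending_moment)
            assert m_fast == pytest.approx(oracle, rel=0.03)
            assert m_slow == pytest.approx(oracle, rel=0.03)

    def test_energy_audit_consistent(self):
        th = simulate_four_point_knee(30)
        assert th.energy["error"].max() < 0.01


class TestDetectEvents:
    def test_no_failures_empty_list(self):
        records = {("tibia", "cortical_fracture"):
                   (np.zeros((5, 4), dtype=bool), np.linspace(0, 1, 4))}
        assert detect_events(np.arange(5.0), records) == []

    def test_single_element_failure_time_and_location(self):
        failed = np.zeros((6, 4), dtype=bool)
        failed[3:, 2] = True
        records = {("femur", "cortical_fracture"):
                   (failed, np.array([0.2, 0.4, 0.6, 0.8]))}
        events = detect_events(np.arange(6) * 0.5, records)
        assert events == [FractureEvent(time=1.5, kind="cortical_fracture",
                                        component="femur", location=0.6)]

    def test_events_sorted_by_time(self):
        f_tib = np.zeros((6, 2), dtype=bool)
        f_tib[2:, 0] = True
        f_fib = np.zeros((6, 2), dtype=bool)
        f_fib[4:, 1] = True
        records = {
            ("fibula", "cortical_fracture"): (f_fib, np.array([0.3, 0.7])),
            ("tibia", "cortical_fracture"): (f_tib, np.array([0.3, 0.7])),
        }
        events = detect_events(np.arange(6.0), records)
        assert [e.component for e in events] == ["tibia", "fibula"]
        assert events[0].time < events[1].time
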