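"""Cross-section formulas, growth-table scaling, and mesh morphing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from agelimb.errors import ClassificationError, DomainError, GeometryError
from agelimb.geometry import (
    GROWTH_TABLE,
    STATIONS,
    CrossSection,
    LongBoneGeometry,
    analytic_cortical_volume,
    interp_section,
    make_synthetic_bone,
    morph_mesh,
    scale_geometry,
    scale_ratio,
    section_areas,
)


def test_section_areas_closed_form():
    p = section_areas(CrossSection(30, 16))
    assert p.TA == pytest.approx(706.86, abs=0.005)
    assert p.MA == pytest.approx(201.06, abs=0.005)
    assert p.CA == pytest.approx(505.80, abs=0.005)


def test_solid_rod_limit():
    p = section_areas(CrossSection(20, 0))
    assert p.MA == 0.0
    assert p.CA == p.TA


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(min_value=1.0, max_value=60.0),
       st.floats(min_value=0.0, max_value=0.95))
def test_area_conservation(d_p, ratio):
    sec = CrossSection(d_p, d_p * ratio)
    p = section_areas(sec)
    assert p.TA == pytest.approx(p.MA + p.CA, rel=1e-12)
    assert p.I < math.pi * d_p**4 / 64 + 1e-9


def test_inertia_matches_quadrature_oracle():
    """Brute-force r^2 dA integration over the annulus (independent route)."""
    d_p, d_m = 30.0, 16.0
    r_p, r_m = d_p / 2, d_m / 2
    # integrate y^2 over full-width strips of outer circle minus inner circle
    oracle = (
        quad(lambda y: 2 * y * y * math.sqrt(r_p**2 - y**2), -r_p, r_p)[0]
        - quad(lambda y: 2 * y * y * math.sqrt(r_m**2 - y**2), -r_m, r_m)[0]
    )
    p = section_areas(CrossSection(d_p, d_m))
    assert p.I == pytest.approx(oracle, rel=1e-6)


def test_degenerate_cortex_rejected():
    with pytest.raises(GeometryError, match="cortex"):
        CrossSection(10, 10)
    with pytest.raises(GeometryError):
        CrossSection(10, 12)


def test_growth_table_reproduced_exactly_at_anchor_age():
    for bone in ("femur", "tibia"):
        for station, (pct_p, pct_m) in GROWTH_TABLE[bone].items():
            r_p, r_m = scale_ratio(bone, station, 70)
            assert (r_p - 1) * 100 == pytest.approx(pct_p, abs=1e-9)
            assert (r_m - 1) * 100 == pytest.approx(pct_m, abs=1e-9)


def test_baseline_age_is_identity_and_fibula_tracks_tibia():
    for s in STATIONS:
        assert scale_ratio("femur", s, 26) == (1.0, 1.0)
        assert scale_ratio("fibula", s, 70) == scale_ratio("tibia", s, 70)
    assert scale_ratio("fibula", 0.35, 70) == pytest.approx((1.037, 1.166))


def test_unknown_station_rejected():
    with pytest.raises(DomainError, match="station"):
        scale_ratio("femur", 0.42, 70)


def test_medullary_expansion_outpaces_periosteal():
    for bone in ("femur", "tibia"):
        for pct_p, pct_m in GROWTH_TABLE[bone].values():
            assert pct_m >= pct_p


def test_scale_geometry_identity_and_cortical_thinning(femur_baseline):
    geom, _ = femur_baseline
    assert scale_geometry(geom, 26) == geom
    aged = scale_geometry(geom, 70)
    mid_base = section_areas(geom.stations[2][1])
    mid_aged = section_areas(aged.stations[2][1])
    assert mid_aged.TA > mid_base.TA       # periosteal expansion
    assert mid_aged.CA < mid_base.CA       # cortical thinning


def test_midshaft_example_composes_ratio_with_areas():
    """A (30, 16) femoral mid-shaft aged to 70: CA 505.8 -> ~465.7 mm^2."""
    r_p, r_m = scale_ratio("femur", 0.50, 70)
    base = section_areas(CrossSection(30.0, 16.0))
    aged = section_areas(CrossSection(30.0 * r_p, 16.0 * r_m))
    assert base.CA == pytest.approx(505.8, abs=0.05)
    assert aged.CA == pytest.approx(465.7, abs=0.1)
    assert aged.TA > base.TA


def test_cortical_area_monotone_nonincreasing_with_age(femur_baseline):
    geom, _ = femur_baseline
    ages = np.arange(26.0, 90.1, 4.0)
    for k in range(len(STATIONS)):
        cas = [
            section_areas(scale_geometry(geom, a).stations[k][1]).CA for a in ages
        ]
        assert all(b <= a + 1e-9 for a, b in zip(cas, cas[1:]))


def test_scaling_that_erases_cortex_reports_station():
    thin = LongBoneGeometry(
        bone="femur", shaft_length=400.0,
        stations=tuple((f, CrossSection(20.0, 19.5)) for f in STATIONS),
    )
    with pytest.raises(GeometryError, match="station 0.20"):
        scale_geometry(thin, 90)


def test_interp_section_station_midpoint_and_clamp(femur_baseline):
    geom, _ = femur_baseline
    assert interp_section(geom, 0.35) == geom.stations[1][1]
    mid = interp_section(geom, 0.275)
    s0, s1 = geom.stations[0][1], geom.stations[1][1]
    assert mid.D_P == pytest.approx((s0.D_P + s1.D_P) / 2)
    assert mid.D_M == pytest.approx((s0.D_M + s1.D_M) / 2)
    assert interp_section(geom, 0.05) == geom.stations[0][1]


class TestMorph:
    def test_identity_at_baseline_age(self, femur_baseline):
        geom, mesh = femur_baseline
        out = morph_mesh(mesh, geom, 26)
        assert np.array_equal(out.points, mesh.points)

    def test_midshaft_radii_scale_by_table_ratios(self):
        # n_axial=41 places a node ring exactly at the 50% station
        geom, mesh = make_synthetic_bone("femur", n_axial=41)
        out = morph_mesh(mesh, geom, 70)
        r = np.hypot(out.points[:, 0], out.points[:, 1])
        at_mid = np.abs(out.points[:, 2] - 0.5 * geom.shaft_length) < 1e-6
        outer = at_mid & (out.layer == 1)
        inner = at_mid & (out.layer == 0)
        assert outer.any() and inner.any()
        assert r[outer].mean() / 14.0 == pytest.approx(1.018, abs=1e-9)
        assert r[inner].mean() / 7.0 == pytest.approx(1.152, abs=1e-9)

    def test_commutes_with_rotation_about_axis(self, femur_baseline):
        geom, mesh = femur_baseline
        ang = 0.7
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rotated = mesh.copy()
        rotated.points = mesh.points @ rot.T
        a = morph_mesh(rotated, geom, 70).points
        b = morph_mesh(mesh, geom, 70).points @ rot.T
        assert np.allclose(a, b, atol=1e-9)

    def test_morphed_tube_volume_matches_analytic(self, femur_baseline):
        geom, mesh = femur_baseline
        out = morph_mesh(mesh, geom, 70)
        aged = scale_geometry(geom, 70)
        assert out.cortical_volume() == pytest.approx(
            analytic_cortical_volume(aged), rel=0.02
        )

    def test_ambiguous_node_raises_classification_error(self, femur_baseline):
        geom, _ = femur_baseline
        # one point halfway between the two layers at mid-shaft
        pts = np.array([[10.5, 0.0, 215.0]])
        with pytest.raises(ClassificationError, match="between layers"):
            morph_mesh(pts, geom, 70,
                       axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])))

    def test_surface_points_classified_without_labels(self, femur_baseline):
        geom, mesh = femur_baseline
        # strip layer labels: classification by radius must reproduce them
        out = morph_mesh(mesh.points, geom, 70,
                         axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])))
        labelled = morph_mesh(mesh, geom, 70)
        assert np.allclose(out, labelled.points)


def test_synthetic_bone_round_trip_and_validity():
    for bone in ("femur", "tibia", "fibula"):
        geom, mesh = make_synthetic_bone(bone)
        assert tuple(f for f, _ in geom.stations) == STATIONS
        for _, sec in geom.stations:
            p = section_areas(sec)
            assert p.CA > 0 and p.I > 0
        assert np.array_equal(morph_mesh(mesh, geom, 26).points, mesh.points)
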