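"""Long-bone cross-section geometry and its change with age.

Adult long-bone shafts remodel throughout life: the periosteal (outer)
surface expands slowly while the medullary cavity expands faster, so the
total area grows while the cortical area shrinks.  This module holds the
annular cross-section formulas, the per-station growth table anchoring the
periosteal/medullary diameter increase of a 70-year-old relative to the
26-year-old baseline, linear-in-age scaling between them, and a radial
mesh morpher that applies the same scaling to a two-layer tube mesh or a
surface mesh.

Station fractions are measured from the proximal end of the shaft.
All lengths in mm, areas mm^2, second moments mm^4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ClassificationError, DomainError, GeometryError
from .materials import _check_age

STATIONS = (0.20, 0.35, 0.50, 0.65, 0.80)
BASELINE_AGE = 26.0
ANCHOR_AGE = 70.0

#: Total percent increase of (D_P, D_M) at age 70 relative to the 26-year-old
#: baseline, per bone and shaft station.  Fibula growth is taken identical to
#: the tibia (no age-resolved fibula anthropometry exists).
GROWTH_TABLE: dict[str, dict[float, tuple[float, float]]] = {
    "femur": {
        0.20: (1.3, 4.3),
        0.35: (1.3, 9.6),
        0.50: (1.8, 15.2),
        0.65: (2.6, 19.4),
        0.80: (4.9, 19.2),
    },
    "tibia": {
        0.20: (5.0, 12.9),
        0.35: (3.7, 16.6),
        0.50: (3.3, 15.7),
        0.65: (4.3, 14.8),
        0.80: (5.3, 11.1),
    },
}
GROWTH_TABLE["fibula"] = GROWTH_TABLE["tibia"]


@dataclass(frozen=True)
class CrossSection:
    """Annular shaft cross-section: periosteal and medullary diameters (mm)."""

    D_P: float
    D_M: float

    def __post_init__(self) -> None:
        if self.D_M < 0 or self.D_P <= self.D_M:
            raise GeometryError(
                f"need D_P > D_M >= 0, got D_P={self.D_P}, D_M={self.D_M} "
                "(zero or negative cortex)"
            )


@dataclass(frozen=True)
class SectionProperties:
    """Derived area and bending properties of an annular section."""

    TA: float  # total area, mm^2
    MA: float  # medullary area, mm^2
    CA: float  # cortical area, mm^2
    I: float   # second moment of the annulus, mm^4
    Z: float   # section modulus I/(D_P/2), mm^3


def section_areas(section: CrossSection) -> SectionProperties:
    """TA = pi D_P^2/4, MA = pi D_M^2/4, CA = TA - MA, plus I and Z."""
    ta = math.pi * section.D_P**2 / 4.0
    ma = math.pi * section.D_M**2 / 4.0
    inertia = math.pi * (section.D_P**4 - section.D_M**4) / 64.0
    return SectionProperties(
        TA=ta, MA=ma, CA=ta - ma, I=inertia, Z=inertia / (section.D_P / 2.0)
    )


def _station_key(station_fraction: float) -> float:
    for s in STATIONS:
        if abs(station_fraction - s) < 1e-9:
            return s
    raise DomainError(
        f"station fraction {station_fraction} is not one of the tabulated "
        f"stations {STATIONS}; use interp_section for intermediate positions"
    )


def scale_ratio(bone: str, station_fraction: float, age: float) -> tuple[float, float]:
    """Diameter multipliers (r_P, r_M) at one station for a given age.

    The tabulated total increase at age 70 is spread linearly over
    (age - 26): ``r(age) = 1 + (age-26)/44 * pct/100``, so r(26) = 1
    exactly and r(70) reproduces the growth table exactly.  The same
    linear rate extrapolates beyond 70 up to age 90.
    """
    if bone not in GROWTH_TABLE:
        raise DomainError(f"unknown bone {bone!r}; known: {tuple(GROWTH_TABLE)}")
    age = _check_age(age)
    pct_p, pct_m = GROWTH_TABLE[bone][_station_key(station_fraction)]
    t = (age - BASELINE_AGE) / (ANCHOR_AGE - BASELINE_AGE)
    return 1.0 + t * pct_p / 100.0, 1.0 + t * pct_m / 100.0


@dataclass(frozen=True)
class LongBoneGeometry:
    """Shaft geometry of one long bone: ordered (fraction, section) stations."""

    bone: str
    shaft_length: float  # mm
    stations: tuple[tuple[float, CrossSection], ...]

    def __post_init__(self) -> None:
        if self.shaft_length <= 0:
            raise GeometryError("shaft length must be positive")
        fracs = [f for f, _ in self.stations]
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise GeometryError("station fractions must be strictly increasing")
        if fracs and (fracs[0] < 0 or fracs[-1] > 1):
            raise GeometryError("station fractions must lie in [0, 1]")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for f, _ in self.stations])

    @property
    def outer_radii(self) -> np.ndarray:
        return np.array([s.D_P / 2.0 for _, s in self.stations])

    @property
    def inner_radii(self) -> np.ndarray:
        return np.array([s.D_M / 2.0 for _, s in self.stations])


def scale_geometry(base: LongBoneGeometry, age: float) -> LongBoneGeometry:
    """Age-scale every station's diameters by its (r_P, r_M) multipliers."""
    age = _check_age(age)
    out = []
    for frac, sec in base.stations:
        r_p, r_m = scale_ratio(base.bone, frac, age)
        d_p, d_m = sec.D_P * r_p, sec.D_M * r_m
        if d_m >= d_p:
            raise GeometryError(
                f"{base.bone} station {frac:.2f}: aging to {age:g} years "
                f"leaves no cortex (D_P={d_p:.2f} <= D_M={d_m:.2f} mm)"
            )
        out.append((frac, CrossSection(d_p, d_m)))
    return replace(base, stations=tuple(out))


def interp_section(geometry: LongBoneGeometry, x: float) -> CrossSection:
    """Piecewise-linear interpolation of diameters along the shaft.

    Positions outside the tabulated station range clamp to the nearest
    station (np.interp end behaviour).
    """
    if not (0.0 <= x <= 1.0):
        raise DomainError(f"shaft fraction {x} outside [0, 1]")
    fr = geometry.fractions
    d_p = float(np.interp(x, fr, [s.D_P for _, s in geometry.stations]))
    d_m = float(np.interp(x, fr, [s.D_M for _, s in geometry.stations]))
    return CrossSection(d_p, d_m)


# ---------------------------------------------------------------------------
# Synthetic baseline bones and tube meshes
# ---------------------------------------------------------------------------

#: Synthetic 26-year-old male baseline shaft diameters (D_P, D_M) in mm at
#: the five stations, literature-typical values.  The true baseline model's
#: geometry is proprietary and unpublished; these stand in for it and are
#: overridable wherever a LongBoneGeometry is accepted.
SYNTHETIC_BASELINES: dict[str, dict] = {
    "femur": {
        "length": 430.0,
        "D_P": (30.0, 29.0, 28.0, 28.0, 29.0),
        "D_M": (17.0, 15.0, 14.0, 14.5, 16.5),
    },
    "tibia": {
        "length": 380.0,
        "D_P": (28.0, 25.0, 24.0, 23.0, 24.0),
        "D_M": (17.5, 13.0, 12.0, 13.0, 17.0),
    },
    "fibula": {
        "length": 380.0,
        "D_P": (13.0, 13.5, 14.0, 14.0, 13.5),
        "D_M": (8.2, 7.5, 7.5, 8.0, 9.5),
    },
}


@dataclass
class TubeMesh:
    """Structured two-layer (endosteal + periosteal) tube surface mesh.

    ``points`` is (N, 3); ``layer`` is 0 for endosteal and 1 for periosteal
    nodes.  The tube axis is z from 0 to the shaft length.  Node ordering is
    layer-major, then axial ring, then circumferential position.
    """

    points: np.ndarray
    layer: np.ndarray
    n_axial: int
    n_circ: int
    length: float

    def copy(self) -> "TubeMesh":
        return TubeMesh(
            self.points.copy(), self.layer.copy(), self.n_axial, self.n_circ, self.length
        )

    def _ring_radii(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Mean radius of each axial ring per layer -> (z, r_inner, r_outer)."""
        r = np.hypot(self.points[:, 0], self.points[:, 1])
        z = self.points[:, 2]
        n = self.n_axial * self.n_circ
        r_in = r[: n].reshape(self.n_axial, self.n_circ).mean(axis=1)
        r_out = r[n:].reshape(self.n_axial, self.n_circ).mean(axis=1)
        z_ring = z[: n].reshape(self.n_axial, self.n_circ).mean(axis=1)
        return z_ring, r_in, r_out

    def cortical_volume(self) -> float:
        """Enclosed cortical (between-layer) volume via polygonal prisms."""
        z, r_in, r_out = self._ring_radii()
        poly = 0.5 * self.n_circ * math.sin(2.0 * math.pi / self.n_circ)
        area = poly * (r_out**2 - r_in**2)
        return float(np.trapezoid(area, z))


def make_synthetic_bone(
    bone: str,
    length: float | None = None,
    n_axial: int = 40,
    n_circ: int = 64,
    seed: int | None = None,
    jitter: float = 0.0,
) -> tuple[LongBoneGeometry, TubeMesh]:
    """Synthetic 26-year-old baseline geometry and a matching tube mesh.

    The optional ``jitter`` (mm, with ``seed``) perturbs node radii to
    emulate surface roughness; zero by default so output is exactly the
    idealised tube.
    """
    if bone not in SYNTHETIC_BASELINES:
        raise DomainError(f"unknown bone {bone!r}")
    spec = SYNTHETIC_BASELINES[bone]
    L = float(length if length is not None else spec["length"])
    if L <= 0:
        raise GeometryError("length must be positive")
    stations = tuple(
        (f, CrossSection(dp, dm))
        for f, dp, dm in zip(STATIONS, spec["D_P"], spec["D_M"])
    )
    geom = LongBoneGeometry(bone=bone, shaft_length=L, stations=stations)

    z = np.linspace(0.0, L, n_axial)
    theta = np.linspace(0.0, 2.0 * math.pi, n_circ, endpoint=False)
    fr = geom.fractions
    r_out = np.interp(z / L, fr, geom.outer_radii)
    r_in = np.interp(z / L, fr, geom.inner_radii)

    rng = np.random.default_rng(seed)
    pts, layers = [], []
    for radii, lab in ((r_in, 0), (r_out, 1)):
        rr = np.repeat(radii, n_circ)
        if jitter > 0:
            rr = rr + rng.normal(0.0, jitter, rr.shape)
        tt = np.tile(theta, n_axial)
        zz = np.repeat(z, n_circ)
        pts.append(np.column_stack([rr * np.cos(tt), rr * np.sin(tt), zz]))
        layers.append(np.full(n_axial * n_circ, lab))
    mesh = TubeMesh(
        points=np.vstack(pts),
        layer=np.concatenate(layers),
        n_axial=n_axial,
        n_circ=n_circ,
        length=L,
    )
    return geom, mesh


# ---------------------------------------------------------------------------
# Mesh morphing
# ---------------------------------------------------------------------------


def fit_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit a shaft axis (origin, unit direction) as the dominant principal
    axis of the node cloud; direction points from low to high coordinate."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    w, v = np.linalg.eigh(cov)
    if w[-1] < 10.0 * max(w[0], 1e-12):
        raise GeometryError("degenerate node cloud: no dominant shaft axis")
    direction = v[:, -1]
    t = (pts - centroid) @ direction
    origin = centroid + t.min() * direction
    if ((pts - origin) @ direction).sum() < 0:
        direction = -direction
    return origin, direction


def morph_points(
    points: np.ndarray,
    base: LongBoneGeometry,
    age: float,
    axis_origin: np.ndarray,
    axis_direction: np.ndarray,
    layer: np.ndarray | None = None,
    ambiguity_tol: float = 0.35,
) -> np.ndarray:
    """Radially scale nodes about the shaft axis by the age ratios.

    Each node is projected on the axis to a shaft fraction, classified as
    periosteal or endosteal by comparing its radius against the baseline
    layer radii at that fraction (unless ``layer`` labels are supplied),
    and its radial coordinate is multiplied by the axially interpolated
    r_P or r_M.  Axial coordinates and topology are untouched.
    """
    age = _check_age(age)
    pts = np.asarray(points, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise GeometryError("degenerate shaft axis direction")
    d = d / nrm
    o = np.asarray(axis_origin, dtype=float)

    rel = pts - o
    t = rel @ d
    frac = np.clip(t / base.shaft_length, 0.0, 1.0)
    radial = rel - np.outer(t, d)
    r = np.linalg.norm(radial, axis=1)

    fr = base.fractions
    r_out_base = np.interp(frac, fr, base.outer_radii)
    r_in_base = np.interp(frac, fr, base.inner_radii)

    if layer is None:
        gap = r_out_base - r_in_base
        d_out = np.abs(r - r_out_base)
        d_in = np.abs(r - r_in_base)
        is_outer = d_out <= d_in
        mind = np.minimum(d_out, d_in)
        bad = mind > ambiguity_tol * gap
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ClassificationError(
                f"node {i} radius {r[i]:.2f} mm at shaft fraction "
                f"{frac[i]:.2f} lies between layers (baseline radii "
                f"{r_in_base[i]:.2f}/{r_out_base[i]:.2f} mm)"
            )
    else:
        is_outer = np.asarray(layer) == 1

    ratios_p = np.empty(len(STATIONS))
    ratios_m = np.empty(len(STATIONS))
    for k, s in enumerate(STATIONS):
        ratios_p[k], ratios_m[k] = scale_ratio(base.bone, s, age)
    scale_p = np.interp(frac, np.array(STATIONS), ratios_p)
    scale_m = np.interp(frac, np.array(STATIONS), ratios_m)
    scale = np.where(is_outer, scale_p, scale_m)

    return o + np.outer(t, d) + radial * scale[:, None]


def morph_mesh(mesh, base: LongBoneGeometry, age: float, axis=None):
    """Morph a :class:`TubeMesh`, a trimesh surface, or an (N, 3) array.

    ``axis`` is an (origin, direction) pair; defaults to the z axis for
    tube meshes and a principal-axis fit otherwise.  Returns the same type
    as the input with updated node coordinates.
    """
    import trimesh as _trimesh

    if isinstance(mesh, TubeMesh):
        origin, direction = axis if axis is not None else (
            np.zeros(3), np.array([0.0, 0.0, 1.0])
        )
        out = mesh.copy()
        out.points = morph_points(
            mesh.points, base, age, origin, direction, layer=mesh.layer
        )
        return out
    if isinstance(mesh, _trimesh.Trimesh):
        origin, direction = axis if axis is not None else fit_axis(mesh.vertices)
        new = mesh.copy()
        new.vertices = morph_points(mesh.vertices, base, age, origin, direction)
        return new
    pts = np.asarray(mesh, dtype=float)
    origin, direction = axis if axis is not None else fit_axis(pts)
    return morph_points(pts, base, age, origin, direction)


def analytic_cortical_volume(geom: LongBoneGeometry) -> float:
    """Exact cortical volume of the piecewise-linear-radius tube between the
    first and last stations (the region a tube mesh spans is [0, 1], with
    radii clamped beyond the end stations; this integrates over [0, 1])."""
    L = geom.shaft_length
    x = np.linspace(0.0, 1.0, 2001)
    r_out = np.interp(x, geom.fractions, geom.outer_radii)
    r_in = np.interp(x, geom.fractions, geom.inner_radii)
    return float(np.trapezoid(math.pi * (r_out**2 - r_in**2), x) * L)
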