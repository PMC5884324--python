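"""Layered fiber-beam discretisation and explicit central-difference solver.

A long bone shaft is modelled as a planar finite-difference beam: nodes
carry lateral displacement only, and each interior node owns a fiber
discretisation of its annular cross-section (cortical strips around a
cancellous core).  Fiber strains follow from the discrete curvature,
stresses from the 1D elastoplastic laws with Cowper–Symonds rate scaling,
and the nodal internal force from the second difference of the section
moment.  Fiber failure ("element deletion") removes a strip from the
moment integral permanently, so a fully failed section degenerates to a
hinge — the fracture mechanism.

The solver advances any number of beams coupled by linear springs,
ligament fiber elements (translational and rotational), and a padded
impactor contact, with a running energy audit.

Unit system: mm, ms, g, N, MPa; energies in N·mm (mJ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .constitutive import FoamPad, LigamentFiberLaw, bilinear_update_arrays, fiber_stress
from .errors import SolverError
from .geometry import CrossSection, LongBoneGeometry, interp_section
from .materials import (
    CancellousParams,
    CorticalParams,
    RateScalingParams,
)

KG_M3_TO_G_MM3 = 1e-6


# ---------------------------------------------------------------------------
# Fiber sections
# ---------------------------------------------------------------------------

def _circle_strip(radius: float, y0: float, y1: float) -> tuple[float, float]:
    """Exact area and second moment of a full-width circle strip y in [y0, y1]."""
    if radius <= 0:
        return 0.0, 0.0
    a = max(-radius, min(y0, radius))
    b = max(-radius, min(y1, radius))
    if b <= a:
        return 0.0, 0.0
    area, _ = quad(lambda y: 2.0 * math.sqrt(max(radius**2 - y**2, 0.0)), a, b)
    inertia, _ = quad(
        lambda y: 2.0 * y * y * math.sqrt(max(radius**2 - y**2, 0.0)), a, b
    )
    return area, inertia


def _layer_fibers(
    r_outer: float, r_inner: float, n_strips: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fibers for an annulus (or disc when r_inner=0) split into horizontal
    strips.  Each fiber's lever arm is chosen so the strip's exact second
    moment is reproduced: y_eff = sqrt(I_strip / A_strip)."""
    edges = np.linspace(-r_outer, r_outer, n_strips + 1)
    ys, areas = [], []
    for y0, y1 in zip(edges[:-1], edges[1:]):
        a_out, i_out = _circle_strip(r_outer, y0, y1)
        a_in, i_in = _circle_strip(r_inner, y0, y1)
        a, i = a_out - a_in, i_out - i_in
        if a <= 1e-12:
            continue
        y_eff = math.sqrt(max(i / a, 0.0)) * (1.0 if (y0 + y1) >= 0 else -1.0)
        ys.append(y_eff)
        areas.append(a)
    return np.array(ys), np.array(areas)


@dataclass
class FiberSet:
    """Per-(interior node, fiber) arrays for one beam."""

    y: np.ndarray        # lever arms, mm (n_int, n_fib)
    area: np.ndarray     # mm^2
    E: np.ndarray        # MPa
    sig_y: np.ndarray    # MPa
    Et: np.ndarray       # MPa
    fail_strain: np.ndarray
    is_cortical: np.ndarray  # bool
    # state
    eps_prev: np.ndarray = field(default=None)
    eps_p: np.ndarray = field(default=None)
    acc: np.ndarray = field(default=None)
    failed: np.ndarray = field(default=None)
    stress: np.ndarray = field(default=None)
    rate_ema: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        shape = self.y.shape
        for name in ("eps_prev", "eps_p", "acc", "stress", "rate_ema"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape))
        if self.failed is None:
            self.failed = np.zeros(shape, dtype=bool)

    @property
    def elastic_EI(self) -> np.ndarray:
        live = ~self.failed
        return ((self.E * self.y**2 * self.area) * live).sum(axis=1)


def build_fibers(
    sections: list[CrossSection],
    cortical: CorticalParams,
    cancellous: CancellousParams,
    n_cortical_strips: int = 16,
    n_cancellous_strips: int = 8,
) -> FiberSet:
    """Fiber discretisation at each interior node's cross-section."""
    rows_y, rows_a, rows_cort = [], [], []
    n_fib_max = 0
    per_section = []
    for sec in sections:
        r_p, r_m = sec.D_P / 2.0, sec.D_M / 2.0
        yc, ac = _layer_fibers(r_p, r_m, n_cortical_strips)
        yn, an = _layer_fibers(r_m, 0.0, n_cancellous_strips)
        y = np.concatenate([yc, yn])
        a = np.concatenate([ac, an])
        cort = np.concatenate([np.ones(len(yc), bool), np.zeros(len(yn), bool)])
        per_section.append((y, a, cort))
        n_fib_max = max(n_fib_max, len(y))
    n = len(per_section)
    Y = np.zeros((n, n_fib_max))
    A = np.zeros((n, n_fib_max))
    C = np.zeros((n, n_fib_max), dtype=bool)
    for i, (y, a, cort) in enumerate(per_section):
        Y[i, : len(y)] = y
        A[i, : len(a)] = a
        C[i, : len(cort)] = cort
    E = np.where(C, cortical.elastic_modulus * 1000.0, cancellous.elastic_modulus)
    E = np.where(A > 0, E, 0.0)
    sig = np.where(C, cortical.yield_stress, cancellous.yield_stress)
    Et = np.where(C, cortical.tangent_modulus, 0.0)
    fs = np.where(C, cortical.failure_strain, cancellous.failure_strain)
    return FiberSet(y=Y, area=A, E=E, sig_y=sig, Et=Et,
                    fail_strain=np.where(A > 0, fs, 1e9), is_cortical=C)


# ---------------------------------------------------------------------------
# Beam model
# ---------------------------------------------------------------------------

@dataclass
class BeamModel:
    """Planar finite-difference beam of one long bone."""

    name: str
    n_nodes: int
    h: float                  # element length, mm
    mass: np.ndarray          # nodal masses, g
    fibers: FiberSet          # at interior nodes 1..n-2
    pinned: np.ndarray        # bool mask of nodes with w = 0
    fractions: np.ndarray     # shaft fraction of each node
    preload_strain: float = 0.0
    # state
    w: np.ndarray = field(default=None)
    v: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.w is None:
            self.w = np.zeros(self.n_nodes)
        if self.v is None:
            self.v = np.zeros(self.n_nodes)
        if self.h <= 0 or np.any(self.mass <= 0):
            raise SolverError("element length and nodal masses must be positive")

    @property
    def length(self) -> float:
        return self.h * (self.n_nodes - 1)

    def end_slope(self, end: str) -> float:
        if end == "start":
            return (self.w[1] - self.w[0]) / self.h
        return (self.w[-1] - self.w[-2]) / self.h


def build_beam(
    geom: LongBoneGeometry,
    cortical: CorticalParams,
    cancellous: CancellousParams,
    n_nodes: int = 33,
    flesh_mass: float = 0.0,
    pinned_ends: bool = True,
    end_mass: float = 0.0,
    preload: float = 0.0,
) -> BeamModel:
    """Discretise an aged long-bone geometry into a fiber beam.

    ``flesh_mass`` (g) lumps the surrounding soft tissue uniformly onto the
    nodes; ``end_mass`` adds to the last node (e.g. a foot).  ``preload``
    (N, compression positive) superposes a uniform axial strain on the
    bending fibers.
    """
    h = geom.shaft_length / (n_nodes - 1)
    fracs = np.linspace(0.0, 1.0, n_nodes)
    sections = [interp_section(geom, x) for x in fracs[1:-1]]
    fibers = build_fibers(sections, cortical, cancellous)

    rho_c = cortical.density * KG_M3_TO_G_MM3
    rho_n = cancellous.density * KG_M3_TO_G_MM3
    mass = np.zeros(n_nodes)
    for i, x in enumerate(fracs):
        sec = interp_section(geom, float(x))
        r_p, r_m = sec.D_P / 2.0, sec.D_M / 2.0
        a_cort = math.pi * (r_p**2 - r_m**2)
        a_canc = math.pi * r_m**2
        mass[i] = (rho_c * a_cort + rho_n * a_canc) * h
    mass[0] *= 0.5
    mass[-1] *= 0.5
    mass += flesh_mass / n_nodes
    mass[-1] += end_mass

    pinned = np.zeros(n_nodes, dtype=bool)
    if pinned_ends:
        pinned[0] = pinned[-1] = True

    eps0 = 0.0
    if preload:
        ea = float((fibers.E * fibers.area).sum(axis=1).mean())
        eps0 = -preload / max(ea, 1e-9)

    return BeamModel(
        name=geom.bone, n_nodes=n_nodes, h=h, mass=mass, fibers=fibers,
        pinned=pinned, fractions=fracs, preload_strain=eps0,
    )


# ---------------------------------------------------------------------------
# Couplings, contacts, events
# ---------------------------------------------------------------------------

@dataclass
class SoftPad:
    """Lumped soft-tissue contact compliance with a compliant toe.

    Force is quadratic in the compression up to ``toe`` mm (flesh
    compressing) and linear with stiffness ``k`` (N/mm) beyond; the exact
    potential is tracked for the energy audit.
    """

    k: float = 350.0     # N/mm
    toe: float = 15.0    # mm

    def force(self, c: float) -> float:
        if c <= 0:
            return 0.0
        if c < self.toe:
            return self.k * c * c / (2.0 * self.toe)
        return self.k * (c - self.toe / 2.0)

    def energy(self, c: float) -> float:
        if c <= 0:
            return 0.0
        if c < self.toe:
            return self.k * c**3 / (6.0 * self.toe)
        e_toe = self.k * self.toe**2 / 6.0
        return e_toe + 0.5 * self.k * ((c - self.toe / 2.0) ** 2 - (self.toe / 2.0) ** 2)

    @property
    def max_stiffness(self) -> float:
        return self.k


class FoamContact:
    """Adapter presenting a crushable FoamPad as a contact force law (N)."""

    def __init__(self, pad: FoamPad):
        self.pad = pad
        # cap just below densification; beyond, extrapolate final slope
        s = np.array([p[0] for p in pad.curve])
        v = np.array([p[1] for p in pad.curve])
        self._s, self._v = s, v

    def force(self, c: float) -> float:
        if c <= 0:
            return 0.0
        strain = c / self.pad.thickness
        if strain >= self._s[-1]:
            slope = (self._v[-1] - self._v[-2]) / max(self._s[-1] - self._s[-2], 1e-9)
            stress = self._v[-1] + slope * (strain - self._s[-1])
        else:
            stress = float(np.interp(strain, self._s, self._v))
        return stress * self.pad.area

    def energy(self, c: float) -> float:
        return self.pad.energy_at(max(c, 0.0))

    @property
    def max_stiffness(self) -> float:
        slopes = np.diff(self._v) / np.maximum(np.diff(self._s), 1e-9)
        return float(slopes.max()) * self.pad.area / self.pad.thickness


class SeriesPad:
    """Two compliances in series (e.g. foam pad + flesh over the bone).

    The combined force–compression law is tabulated at construction by
    adding the members' compressions at equal force; force, stored energy
    and peak stiffness are interpolated from the table.
    """

    def __init__(self, *pads, f_max: float = 40000.0, n: int = 800):
        self.pads = pads
        c_grids = []
        for p in pads:
            # tabulate each pad on its own compression grid, then invert
            c = np.linspace(0.0, 400.0, 4000)
            f = np.array([p.force(x) for x in c])
            c_grids.append((f, c))
        f_grid = np.linspace(0.0, f_max, n)
        c_tot = np.zeros_like(f_grid)
        for f, c in c_grids:
            c_tot += np.interp(f_grid, f, c)
        self._c = c_tot
        self._f = f_grid
        self._e = np.concatenate([[0.0], np.cumsum(
            0.5 * (f_grid[1:] + f_grid[:-1]) * np.diff(c_tot))])

    def force(self, c: float) -> float:
        if c <= 0:
            return 0.0
        return float(np.interp(c, self._c, self._f))

    def energy(self, c: float) -> float:
        if c <= 0:
            return 0.0
        return float(np.interp(c, self._c, self._e))

    @property
    def max_stiffness(self) -> float:
        df = np.diff(self._f)
        dc = np.maximum(np.diff(self._c), 1e-9)
        return float((df / dc).max())


@dataclass
class LinearSpring:
    """Two-way linear spring between nodes of two beams (or one beam and
    ground when ``beam_b`` is None)."""

    beam_a: int
    node_a: int
    k: float  # N/mm
    beam_b: int | None = None
    node_b: int | None = None


@dataclass
class LigamentShear:
    """Ligament fiber bundle resisting relative lateral displacement.

    Engages when ``sign * (w_a - w_b) > 0``; stretch = 1 + |s|/L0.
    """

    beam_a: int
    node_a: int
    beam_b: int
    node_b: int
    law: LigamentFiberLaw
    area: float   # mm^2
    L0: float     # mm
    sign: float
    name: str
    failed: bool = False
    energy: float = 0.0
    _s_prev: float = 0.0
    _f_prev: float = 0.0


@dataclass
class LigamentRotation:
    """Ligament bundle resisting relative end rotation of two beams.

    The stretch of the bundle grows with the joint opening:
    stretch = 1 + gain * theta, where gain = (insertion lever)/(reference
    length); moment = force * lever.  Engages for ``sign * theta > 0``.
    """

    beam_a: int   # femur; moment applied at its far end
    beam_b: int   # tibia; moment applied at its start
    law: LigamentFiberLaw
    area: float
    lever: float  # mm
    gain: float   # lever / reference length
    sign: float
    name: str
    failed: bool = False
    energy: float = 0.0
    _t_prev: float = 0.0
    _m_prev: float = 0.0


@dataclass
class RotSpring:
    """Linear elastic rotational capsule spring across the joint (N*mm/rad)."""

    beam_a: int
    beam_b: int
    k: float


@dataclass(frozen=True)
class FractureEvent:
    """First failure of a component: bone fracture or ligament rupture."""

    time: float       # ms
    kind: str         # cortical_fracture | cancellous_failure | ligament_rupture
    component: str    # femur/tibia/fibula/MCL/LCL/ACL/PCL
    location: float   # axial fraction (0 for joint ligaments)


def detect_events(times, failure_records) -> list[FractureEvent]:
    """First failure time per (component, kind) from time-ordered states.

    ``failure_records`` maps ``(component, kind)`` to a pair
    ``(failed, locations)`` where ``failed`` is a (n_times, n_elements)
    boolean array and ``locations`` the axial fraction of each element.
    The event location is the centroid fraction of the first failed
    element(s).
    """
    events = []
    for (component, kind), (failed, locations) in failure_records.items():
        failed = np.asarray(failed, dtype=bool)
        any_t = failed.any(axis=1)
        if not any_t.any():
            continue
        i = int(np.argmax(any_t))
        locs = np.asarray(locations, dtype=float)[failed[i]]
        events.append(
            FractureEvent(
                time=float(times[i]), kind=kind, component=component,
                location=float(locs.mean()),
            )
        )
    events.sort(key=lambda e: e.time)
    return events


# ---------------------------------------------------------------------------
# Time history
# ---------------------------------------------------------------------------

@dataclass
class TimeHistory:
    """Decimated output traces of one rig simulation."""

    time: np.ndarray                  # ms
    impactor_force: np.ndarray        # kN
    impactor_displacement: np.ndarray  # mm
    knee_angle: np.ndarray            # deg
    knee_shear: np.ndarray            # mm
    bending_moment: np.ndarray        # N*m
    events: list[FractureEvent]
    energy: dict                      # audit traces and scalars

    def first_event(self, component: str, kind: str | None = None):
        for e in self.events:
            if e.component == component and (kind is None or e.kind == kind):
                return e
        return None


# ---------------------------------------------------------------------------
# Explicit solver
# ---------------------------------------------------------------------------

class ExplicitSystem:
    """Central-difference explicit integrator for coupled fiber beams.

    The impactor is either kinematic (prescribed constant speed, an
    infinite-mass test machine) or a free mass with initial velocity; it
    loads one beam node through a pad contact law.
    """

    def __init__(
        self,
        beams: list[BeamModel],
        pad=None,
        strike: tuple[int, int] = (0, 0),
        impactor_speed: float = 0.0,    # mm/ms
        impactor_mass: float | None = None,  # g; None = kinematic
        springs: list[LinearSpring] | None = None,
        shear_ligs: list[LigamentShear] | None = None,
        rot_ligs: list[LigamentRotation] | None = None,
        rot_springs: list[RotSpring] | None = None,
        point_loads: list[tuple[int, int, float]] | None = None,  # (beam, node, N)
        rate_params: RateScalingParams | None = None,
        damping: float = 0.0,           # mass-proportional, 1/ms
        moment_node: tuple[int, int] | None = None,
        face_halfwidth: float = 0.0,    # mm; impactor face spread along the beam
        contact_nodes: list[tuple[int, int, float]] | None = None,
    ):
        self.beams = beams
        self.pad = pad
        self.strike = strike
        if contact_nodes is None:
            # distribute the contact over nodes covered by the impactor face
            sb, sn = strike
            h = beams[sb].h
            z0 = sn * h
            nodes = [
                j for j in range(beams[sb].n_nodes)
                if abs(j * h - z0) <= max(face_halfwidth, 1e-9)
            ] or [sn]
            contact_nodes = [(sb, j, 1.0 / len(nodes)) for j in nodes]
        self.contact_nodes = contact_nodes
        self.impactor_speed = impactor_speed
        self.impactor_mass = impactor_mass
        self.springs = springs or []
        self.shear_ligs = shear_ligs or []
        self.rot_ligs = rot_ligs or []
        self.rot_springs = rot_springs or []
        self.point_loads = point_loads or []
        self.rate = rate_params or RateScalingParams()
        self.rate_tau = 0.2  # ms, strain-rate low-pass time constant
        self.damping = damping
        self.moment_node = moment_node or (strike[0], strike[1])

        self.u = 0.0            # impactor displacement
        self.v_imp = impactor_speed
        self.t = 0.0
        self.w_ext = 0.0
        self._e_damp = 0.0
        self._f_pad_prev = 0.0
        self.events: list[FractureEvent] = []
        self._event_seen: set[tuple[str, str]] = set()

    # -- time step ----------------------------------------------------------

    def stable_dt(self, safety: float = 0.9) -> float:
        dts = []
        for b in self.beams:
            ei = b.fibers.elastic_EI
            m_int = b.mass[1:-1]
            omega = (4.0 / b.h**2) * np.sqrt(np.maximum(ei, 1e-9) * b.h / m_int)
            dts.append(2.0 / omega.max())
        masses = [b.mass.min() for b in self.beams]
        m_min = min(masses)
        if self.impactor_mass:
            m_min = min(m_min, self.impactor_mass)
        k_candidates = [self.pad.max_stiffness] if self.pad is not None else []
        k_candidates += [s.k for s in self.springs]
        for lig in self.shear_ligs:
            k_candidates.append(lig.law.C5 * lig.area / lig.L0)
        for k in k_candidates:
            if k > 0:
                dts.append(2.0 / math.sqrt(2.0 * k / m_min))
        return safety * min(dts)

    # -- internal forces ----------------------------------------------------

    def _beam_internal(self, b: BeamModel, dt: float):
        w = b.w
        kappa = (w[:-2] - 2.0 * w[1:-1] + w[2:]) / b.h**2
        fib = b.fibers
        eps = fib.y * kappa[:, None] + b.preload_strain
        # smoothed strain rate: the raw per-step estimate carries
        # near-Nyquist element oscillations, so it is low-pass filtered
        # with a short time constant to keep the Cowper-Symonds yield
        # scale insensitive to the integration step
        inst = np.abs(eps - fib.eps_prev) / dt * 1000.0  # 1/ms -> 1/s
        alpha = dt / (self.rate_tau + dt)
        fib.rate_ema += alpha * (inst - fib.rate_ema)
        scale = np.where(
            fib.is_cortical,
            1.0 + (fib.rate_ema / self.rate.C) ** (1.0 / self.rate.P),
            1.0,
        )
        was_failed = fib.failed.copy()
        stress, ep, acc, dead = bilinear_update_arrays(
            eps, fib.eps_p, fib.acc, fib.failed,
            fib.E, fib.sig_y, fib.Et, fib.fail_strain, scale,
        )
        # energy increment (trapezoid on each fiber), volume = area * h
        de = (eps - fib.eps_prev)
        self._e_int += float(
            (0.5 * (stress + fib.stress) * de * fib.area).sum() * b.h
        )
        # events: newly failed fibers
        new = dead & ~was_failed
        if new.any():
            rows = np.nonzero(new.any(axis=1))[0]
            for i in rows:
                cort_new = new[i] & fib.is_cortical[i]
                canc_new = new[i] & ~fib.is_cortical[i]
                loc = float(b.fractions[i + 1])
                if cort_new.any():
                    self._record_event(b.name, "cortical_fracture", loc)
                if canc_new.any():
                    self._record_event(b.name, "cancellous_failure", loc)
        fib.eps_prev = eps
        fib.eps_p, fib.acc, fib.failed, fib.stress = ep, acc, dead, stress

        moment = (stress * fib.y * fib.area).sum(axis=1)  # N*mm at interior nodes
        m_full = np.zeros(b.n_nodes)
        m_full[1:-1] = moment
        f = np.zeros(b.n_nodes)
        f[1:-1] = -(m_full[:-2] - 2.0 * m_full[1:-1] + m_full[2:]) / b.h
        # end nodes: moment is zero beyond the ends (free/pinned)
        f[0] = -(m_full[1] - 2.0 * m_full[0]) / b.h
        f[-1] = -(m_full[-2] - 2.0 * m_full[-1]) / b.h
        return f, m_full

    def _record_event(self, component: str, kind: str, location: float) -> None:
        key = (component, kind)
        if key not in self._event_seen:
            self._event_seen.add(key)
            self.events.append(
                FractureEvent(time=self.t, kind=kind, component=component,
                              location=location)
            )

    # -- main loop ----------------------------------------------------------

    def run(
        self,
        t_end: float,
        output_dt: float = 0.1,
        dt: float | None = None,
        stop_when=None,
        energy_tol: float = 0.05,
    ) -> TimeHistory:
        dt = dt if dt is not None else self.stable_dt()
        n_steps = int(math.ceil(t_end / dt))
        rec_every = max(int(round(output_dt / dt)), 1)

        ke0 = 0.0
        if self.impactor_mass:
            ke0 = 0.5 * self.impactor_mass * self.impactor_speed**2
        self._e_int = 0.0

        out = {k: [] for k in ("t", "f", "u", "ang", "sh", "mom",
                               "w_ext", "ke", "e_int", "e_lig", "e_spr",
                               "e_pad", "err")}

        sb, sn = self.strike
        for step in range(n_steps + 1):
            forces = [np.zeros(b.n_nodes) for b in self.beams]
            moments = []
            for bi, b in enumerate(self.beams):
                f, m_full = self._beam_internal(b, dt)
                forces[bi] += f
                moments.append(m_full)

            # linear springs
            e_spr = 0.0
            for s in self.springs:
                wa = self.beams[s.beam_a].w[s.node_a]
                wb = self.beams[s.beam_b].w[s.node_b] if s.beam_b is not None else 0.0
                x = wa - wb
                fs = -s.k * x
                forces[s.beam_a][s.node_a] += fs
                if s.beam_b is not None:
                    forces[s.beam_b][s.node_b] -= fs
                e_spr += 0.5 * s.k * x * x

            # ligament shear elements
            for lig in self.shear_ligs:
                wa = self.beams[lig.beam_a].w[lig.node_a]
                wb = self.beams[lig.beam_b].w[lig.node_b]
                srel = lig.sign * (wa - wb)
                fmag = 0.0
                if not lig.failed and srel > 0:
                    lam = 1.0 + srel / lig.L0
                    if lam - 1.0 >= lig.law.failure_strain:
                        lig.failed = True
                        self._record_event(lig.name, "ligament_rupture", 0.0)
                    else:
                        fmag = lig.area * fiber_stress(lam, lig.law, include_matrix=True)
                lig.energy += 0.5 * (fmag + lig._f_prev) * (srel - lig._s_prev)
                lig._s_prev, lig._f_prev = srel, fmag
                forces[lig.beam_a][lig.node_a] -= lig.sign * fmag
                forces[lig.beam_b][lig.node_b] += lig.sign * fmag

            # ligament rotational bundles + capsule springs
            theta = None
            if self.rot_ligs or self.rot_springs:
                # joint angle between first two beams (femur end, tibia start)
                theta = (self.beams[1].end_slope("start")
                         - self.beams[0].end_slope("end"))
            for lig in self.rot_ligs:
                trel = lig.sign * theta
                mmag = 0.0
                if not lig.failed and trel > 0:
                    lam = 1.0 + lig.gain * trel
                    if lam - 1.0 >= lig.law.failure_strain:
                        lig.failed = True
                        self._record_event(lig.name, "ligament_rupture", 0.0)
                    else:
                        mmag = (lig.area
                                * fiber_stress(lam, lig.law, include_matrix=True)
                                * lig.lever)
                lig.energy += 0.5 * (mmag + lig._m_prev) * (trel - lig._t_prev)
                lig._t_prev, lig._m_prev = trel, mmag
                # restoring: opposes the joint opening it engages on
                self._apply_joint_moment(forces, -lig.sign * mmag)
            for rs in self.rot_springs:
                m = -rs.k * theta
                self._apply_joint_moment(forces, m)
                e_spr += 0.5 * rs.k * theta * theta

            # constant point loads (e.g. quasi-static rigs)
            for bl, nd, fval in self.point_loads:
                forces[bl][nd] += fval

            # impactor contact (split over the face's footprint nodes)
            f_pad = 0.0
            if self.pad is not None:
                for cb, nd, wt in self.contact_nodes:
                    c = self.u - self.beams[cb].w[nd]
                    fj = self.pad.force(c) * wt
                    forces[cb][nd] += fj
                    f_pad += fj

            # integrate beams
            for bi, b in enumerate(self.beams):
                f = forces[bi]
                v_old = b.v.copy()
                a = f / b.mass - self.damping * b.v
                a[b.pinned] = 0.0
                b.v += a * dt
                b.v[b.pinned] = 0.0
                dw = b.v * dt
                b.w += dw
                if self.damping:
                    self._e_damp += float(
                        (self.damping * b.mass * v_old * b.v).sum() * dt
                    )
                for bl, nd, fval in self.point_loads:
                    if bl == bi:
                        self.w_ext += fval * dw[nd]
                if not np.all(np.isfinite(b.w)):
                    raise SolverError(
                        f"non-finite displacement in beam {b.name!r} at t={self.t:.3f} ms"
                    )

            # integrate impactor
            u_prev = self.u
            if self.pad is not None:
                if self.impactor_mass is None:
                    self.u = self.impactor_speed * (self.t + dt)
                    self.w_ext += 0.5 * (f_pad + self._f_pad_prev) * (self.u - u_prev)
                else:
                    a_imp = -f_pad / self.impactor_mass
                    self.v_imp += a_imp * dt
                    self.u += self.v_imp * dt
            self._f_pad_prev = f_pad
            self.t += dt

            if step % rec_every == 0:
                ke = sum(0.5 * float((b.mass * b.v**2).sum()) for b in self.beams)
                if self.impactor_mass:
                    ke += 0.5 * self.impactor_mass * self.v_imp**2
                e_pad = 0.0
                if self.pad is not None:
                    e_pad = sum(
                        wt * self.pad.energy(max(self.u - self.beams[cb].w[nd], 0.0))
                        for cb, nd, wt in self.contact_nodes
                    )
                e_lig = sum(l.energy for l in self.shear_ligs + self.rot_ligs)
                e_tot = ke + self._e_int + e_lig + e_spr + e_pad + self._e_damp
                e_in = ke0 + self.w_ext
                denom = max(ke0, self.w_ext, 1000.0)  # >= 1 J
                err = abs(e_in - e_tot) / denom
                mb, mn = self.moment_node
                out["t"].append(self.t)
                out["f"].append(f_pad / 1000.0)
                out["u"].append(self.u)
                shear = 0.0
                ang = 0.0
                if len(self.beams) > 1 and (self.shear_ligs or self.rot_ligs):
                    shear = (self.beams[1].w[0] - self.beams[0].w[-1])
                    ang = math.degrees(self.beams[1].end_slope("start")
                                       - self.beams[0].end_slope("end"))
                out["ang"].append(ang)
                out["sh"].append(shear)
                out["mom"].append(moments[mb][mn] / 1000.0)  # N*mm -> N*m
                out["w_ext"].append(self.w_ext)
                out["ke"].append(ke)
                out["e_int"].append(self._e_int)
                out["e_lig"].append(e_lig)
                out["e_spr"].append(e_spr)
                out["e_pad"].append(e_pad)
                out["err"].append(err)
                if err > energy_tol and max(ke0, self.w_ext) > 2000.0:
                    raise SolverError(
                        f"energy drift {100 * err:.1f}% at t={self.t:.2f} ms "
                        "(time-step instability)"
                    )
                if stop_when is not None and stop_when(self):
                    break

        energy = {
            "initial_kinetic_J": ke0 / 1000.0,
            "external_work_J": self.w_ext / 1000.0,
            "time": np.array(out["t"]),
            "kinetic": np.array(out["ke"]),
            "internal": np.array(out["e_int"]),
            "ligament": np.array(out["e_lig"]),
            "springs": np.array(out["e_spr"]),
            "pad": np.array(out["e_pad"]),
            "external_work": np.array(out["w_ext"]),
            "error": np.array(out["err"]),
        }
        return TimeHistory(
            time=np.array(out["t"]),
            impactor_force=np.array(out["f"]),
            impactor_displacement=np.array(out["u"]),
            knee_angle=np.array(out["ang"]),
            knee_shear=np.array(out["sh"]),
            bending_moment=np.array(out["mom"]),
            events=sorted(self.events, key=lambda e: e.time),
            energy=energy,
        )

    def _apply_joint_moment(self, forces, m: float) -> None:
        """Apply moment +m to the tibia start and -m to the femur end as
        force couples on the adjacent node pairs."""
        fb, tb = self.beams[0], self.beams[1]
        hf, ht = fb.h, tb.h
        # couple on tibia (beam 1) start: moment m about its start
        forces[1][1] += m / ht
        forces[1][0] -= m / ht
        # reaction couple on femur (beam 0) end
        forces[0][-2] += m / hf
        forces[0][-1] -= m / hf
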