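"""Validation rigs: impact load cases with fracture and rupture detection.

Four rigs reproduce, at layered-beam fidelity, the classic cadaver load
cases used to characterise pedestrian lower-extremity tolerance:

* three-point bending of the isolated thigh (femur) or calf (tibia +
  fibula in parallel) at 1.5 m/s;
* dynamic four-point valgus bending of the knee at 1 deg/ms, resisted by
  the MCL bundle, until ligament rupture;
* whole-limb lateral bending (6.25 kg impactor at 40 km/h on the ankle)
  and shear (same impactor on the knee), with a 400 N standing preload at
  the hip and a 100 x 120 x 50 mm foam pad on the impactor face.

Absolute force/displacement magnitudes of the full 3D cadaver tests are
not reproduction targets at this fidelity; age orderings and response
shapes are.  All rigs are deterministic given their configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beam import (
    BeamModel,
    ExplicitSystem,
    FoamContact,
    FractureEvent,
    LigamentRotation,
    LigamentShear,
    LinearSpring,
    RotSpring,
    SeriesPad,
    SoftPad,
    TimeHistory,
    build_beam,
    detect_events,  # noqa: F401  (re-exported rig-level API)
)
from .constitutive import FoamPad, fiber_stress
from .errors import DomainError
from .geometry import make_synthetic_bone, scale_geometry
from .materials import material_table

IMPACT_SPEED_LIMB = 40.0 / 3.6  # mm/ms (40 km/h)
IMPACTOR_MASS_LIMB = 6250.0     # g (6.25 kg)
HIP_PRELOAD = 400.0             # N
THREE_POINT_SPEED = 1.5         # mm/ms
KNEE_RATE = 1.0                 # deg/ms


@dataclass(frozen=True)
class RigSpec:
    """Configuration of one validation load case."""

    kind: str                       # three_point | four_point_knee | limb_bending | limb_shear
    impactor_mass: float = IMPACTOR_MASS_LIMB   # g
    impactor_speed: float | None = None         # mm/ms; rig default if None
    angular_rate: float = KNEE_RATE             # deg/ms
    preload: float = HIP_PRELOAD                # N
    strike_fraction: float = 0.5
    foam: FoamPad = field(default_factory=FoamPad)

    def __post_init__(self) -> None:
        if self.kind not in (
            "three_point", "four_point_knee", "limb_bending", "limb_shear"
        ):
            raise DomainError(f"unknown rig kind {self.kind!r}")
        if self.impactor_mass <= 0 or (
            self.impactor_speed is not None and self.impactor_speed < 0
        ):
            raise DomainError("impactor mass must be positive, speed nonnegative")

    @property
    def speed(self) -> float:
        """Impactor speed with the rig's own default applied (mm/ms)."""
        if self.impactor_speed is not None:
            return self.impactor_speed
        return THREE_POINT_SPEED if self.kind == "three_point" else IMPACT_SPEED_LIMB


#: Knee joint defaults: effective ligament insertion geometry and capsule
#: stiffness.  Levers and reference lengths are frontal-plane effective
#: values (valgus rotation opens the medial side about the lateral condyle
#: contact, so the MCL lever is close to the full knee width).
KNEE_DEFAULTS = {
    "mcl": {"area": 9.0, "lever": 80.0, "ref_length": 60.0},
    "lcl": {"area": 7.0, "lever": 60.0, "ref_length": 55.0},
    "acl": {"area": 6.0, "ref_length": 30.0},
    "pcl": {"area": 7.0, "ref_length": 34.0},
    "capsule_rotation": 28648.0,   # N*mm/rad  (~0.5 N*m/deg)
    "capsule_shear": 20.0,         # N/mm
    "fixture_plate": 600.0,        # N/mm, distal-femur horizontal restraint
    "knee_flesh": (400.0, 8.0),    # (N/mm, toe mm) flesh in series with foam
}

#: Lumped soft-tissue (flesh) masses per segment, g.
FLESH_MASS = {"thigh": 7000.0, "calf_tibia": 2800.0, "calf_fibula": 700.0}
FOOT_MASS = 1000.0  # g


def _aged_beam(bone: str, age: float, n_nodes: int, flesh: float,
               pinned_ends: bool = True, end_mass: float = 0.0,
               preload: float = 0.0) -> BeamModel:
    base, _ = make_synthetic_bone(bone)
    geom = scale_geometry(base, age)
    mats = material_table(age)
    return build_beam(
        geom, mats.cortical[bone], mats.cancellous[bone],
        n_nodes=n_nodes, flesh_mass=flesh, pinned_ends=pinned_ends,
        end_mass=end_mass, preload=preload,
    )


def _fracture_stop(component: str, grace: float = 2.0):
    def stop(sys: ExplicitSystem) -> bool:
        for e in sys.events:
            if e.component == component and e.kind == "cortical_fracture":
                return sys.t > e.time + grace
        return False
    return stop


def simulate_three_point(
    segment: str,
    age: float,
    speed: float = THREE_POINT_SPEED,
    t_end: float = 48.0,
    n_nodes: int = 33,
    dt: float | None = None,
    pad: SoftPad | None = None,
) -> TimeHistory:
    """Three-point bending of the thigh or calf at mid-shaft.

    The potted specimen ends are pinned supports; a kinematic impactor
    (test-machine driven) advances at constant speed and loads the bone
    through a lumped soft-tissue pad, so the force trace shows the slow
    initial flesh-compression rise before structural loading.  For the
    calf, the impactor loads the fibula first and the tibia through an
    interosseous coupling spring, so the slender fibula fractures first.
    """
    if segment not in ("thigh", "calf"):
        raise DomainError(f"segment must be 'thigh' or 'calf', got {segment!r}")
    mid = (n_nodes - 1) // 2
    if segment == "thigh":
        femur = _aged_beam("femur", age, n_nodes, FLESH_MASS["thigh"])
        sys = ExplicitSystem(
            beams=[femur],
            pad=pad or SoftPad(k=350.0, toe=15.0),
            strike=(0, mid),
            impactor_speed=speed,
        )
        stop = _fracture_stop("femur")
    else:
        fibula = _aged_beam("fibula", age, n_nodes, FLESH_MASS["calf_fibula"])
        tibia = _aged_beam("tibia", age, n_nodes, FLESH_MASS["calf_tibia"])
        sys = ExplicitSystem(
            beams=[fibula, tibia],
            pad=pad or SoftPad(k=350.0, toe=12.0),
            strike=(0, mid),
            springs=[LinearSpring(beam_a=0, node_a=mid, k=200.0,
                                  beam_b=1, node_b=mid)],
            impactor_speed=speed,
            moment_node=(1, mid),
        )
        stop = _fracture_stop("tibia")
    return sys.run(t_end, dt=dt, stop_when=stop)


# ---------------------------------------------------------------------------
# Four-point knee bending (quasi-kinematic)
# ---------------------------------------------------------------------------

def _mcl_bundle(law, n_fibers: int = 3):
    g = KNEE_DEFAULTS["mcl"]
    spread = np.linspace(0.95, 1.05, n_fibers)
    levers = g["lever"] * spread
    areas = np.full(n_fibers, g["area"] / n_fibers)
    gains = levers / g["ref_length"]
    return levers, areas, gains


def simulate_four_point_knee(
    age: float,
    rate: float = KNEE_RATE,
    t_end: float | None = None,
    dt: float = 0.02,
    output_dt: float = 0.1,
    max_angle: float = 30.0,
) -> TimeHistory:
    """Dynamic four-point valgus bending of the knee at a prescribed
    angular rate (deg/ms).

    Rigid femur/tibia extension bars prescribe the knee opening angle;
    the MCL fiber bundle is the dominant lateral restraint, in parallel
    with a small elastic capsule stiffness.  The bending moment rises
    monotonically, peaks when the MCL is about to rupture, and collapses
    as the bundle fails fiber by fiber.  The ligament law is rate-
    independent, so the moment–angle curve is the quasi-static curve
    traversed at the given rate.
    """
    if rate <= 0:
        raise DomainError("angular rate must be positive")
    law = material_table(age).ligament
    levers, areas, gains = _mcl_bundle(law)
    k_cap = KNEE_DEFAULTS["capsule_rotation"]  # N*mm/rad

    if t_end is None:
        t_end = max_angle / rate
    n_steps = int(math.ceil(t_end / dt))
    rec_every = max(int(round(output_dt / dt)), 1)

    failed = np.zeros(len(levers), dtype=bool)
    fiber_e = np.zeros(len(levers))
    lam_prev = np.ones(len(levers))
    f_prev = np.zeros(len(levers))
    w_ext = 0.0
    m_prev = 0.0
    cap_e = 0.0
    events: list[FractureEvent] = []

    out_t, out_ang, out_mom, out_err = [], [], [], []
    t = 0.0
    for step in range(n_steps + 1):
        theta_deg = rate * t
        theta = math.radians(theta_deg)
        lam = 1.0 + gains * theta
        newly = (~failed) & (lam - 1.0 >= law.failure_strain)
        if newly.any() and not failed.any():
            events.append(FractureEvent(time=t, kind="ligament_rupture",
                                        component="MCL", location=0.0))
        failed |= newly
        forces = np.where(
            failed, 0.0,
            areas * np.array([fiber_stress(x, law, include_matrix=True) for x in lam]),
        )
        fiber_e += 0.5 * (forces + f_prev) * (lam - lam_prev) * (
            levers / gains
        )  # dL = L0 * dlam; L0 = lever/gain
        lam_prev, f_prev = lam, forces
        moment = float((forces * levers).sum()) + k_cap * theta  # N*mm
        cap_e = 0.5 * k_cap * theta * theta

        if step > 0:
            w_ext += 0.5 * (moment + m_prev) * math.radians(rate * dt)
        m_prev = moment

        if step % rec_every == 0:
            denom = max(w_ext, 1000.0)
            err = abs(w_ext - (fiber_e.sum() + cap_e)) / denom
            out_t.append(t)
            out_ang.append(theta_deg)
            out_mom.append(moment / 1000.0)  # N*m
            out_err.append(err)
            if failed.all() and events and t > events[0].time + 2.0 / rate:
                break
        t += dt

    n = len(out_t)
    zeros = np.zeros(n)
    energy = {
        "initial_kinetic_J": 0.0,
        "external_work_J": w_ext / 1000.0,
        "time": np.array(out_t),
        "external_work": np.array([w_ext] * n),
        "error": np.array(out_err),
    }
    return TimeHistory(
        time=np.array(out_t),
        impactor_force=zeros,
        impactor_displacement=zeros,
        knee_angle=np.array(out_ang),
        knee_shear=zeros,
        bending_moment=np.array(out_mom),
        events=events,
        energy=energy,
    )


# ---------------------------------------------------------------------------
# Whole-limb bending / shear
# ---------------------------------------------------------------------------

def simulate_limb(
    age: float,
    mode: str,
    t_end: float = 25.0,
    n_nodes: int = 25,
    dt: float | None = None,
    rig: RigSpec | None = None,
) -> TimeHistory:
    """Whole lower-limb lateral impact: bending (ankle strike) or shear
    (knee strike) with a padded free-flying impactor.

    The femur is pinned at the hip and restrained near the knee by a
    stiff fixture-plate spring; the tibia hangs from the knee ligaments
    (MCL/LCL resisting relative rotation, ACL/PCL relative shear) plus a
    weak capsule.  Ligament ruptures and bone fractures are recorded; the
    energy audit starts from the impactor's kinetic energy.
    """
    if mode not in ("bending", "shear"):
        raise DomainError(f"mode must be 'bending' or 'shear', got {mode!r}")
    if rig is None:
        rig = RigSpec(kind=f"limb_{mode}")

    femur = _aged_beam("femur", age, n_nodes, FLESH_MASS["thigh"],
                       pinned_ends=False, preload=rig.preload)
    femur.pinned[0] = True
    tibia = _aged_beam("tibia", age, n_nodes, FLESH_MASS["calf_tibia"],
                       pinned_ends=False, end_mass=FOOT_MASS,
                       preload=rig.preload)

    law = material_table(age).ligament
    kd = KNEE_DEFAULTS
    rot_ligs = [
        LigamentRotation(beam_a=0, beam_b=1, law=law, area=kd["mcl"]["area"],
                         lever=kd["mcl"]["lever"],
                         gain=kd["mcl"]["lever"] / kd["mcl"]["ref_length"],
                         sign=+1.0, name="MCL"),
        LigamentRotation(beam_a=0, beam_b=1, law=law, area=kd["lcl"]["area"],
                         lever=kd["lcl"]["lever"],
                         gain=kd["lcl"]["lever"] / kd["lcl"]["ref_length"],
                         sign=-1.0, name="LCL"),
    ]
    shear_ligs = [
        LigamentShear(beam_a=1, node_a=0, beam_b=0, node_b=n_nodes - 1,
                      law=law, area=kd["acl"]["area"],
                      L0=kd["acl"]["ref_length"], sign=+1.0, name="ACL"),
        LigamentShear(beam_a=1, node_a=0, beam_b=0, node_b=n_nodes - 1,
                      law=law, area=kd["pcl"]["area"],
                      L0=kd["pcl"]["ref_length"], sign=-1.0, name="PCL"),
    ]
    springs = [
        # fixture plate restraining the distal femur horizontally
        LinearSpring(beam_a=0, node_a=n_nodes - 1, k=kd["fixture_plate"]),
        # weak capsule shear coupling
        LinearSpring(beam_a=1, node_a=0, k=kd["capsule_shear"],
                     beam_b=0, node_b=n_nodes - 1),
    ]
    strike_node = n_nodes - 1 if mode == "bending" else 0
    contact_nodes = None
    if mode == "shear":
        # the impactor face spans the joint line: it loads the proximal
        # tibia and the distal femur together
        half = rig.foam.depth / 2.0
        tib_nodes = [j for j in range(n_nodes) if j * tibia.h <= half] or [0]
        fem_nodes = [
            j for j in range(n_nodes)
            if (n_nodes - 1 - j) * femur.h <= half
        ] or [n_nodes - 1]
        total = len(tib_nodes) + len(fem_nodes)
        contact_nodes = [(1, j, 1.0 / total) for j in tib_nodes]
        contact_nodes += [(0, j, 1.0 / total) for j in fem_nodes]
    flesh_k, flesh_toe = kd["knee_flesh"]
    sys = ExplicitSystem(
        beams=[femur, tibia],
        pad=SeriesPad(FoamContact(rig.foam), SoftPad(k=flesh_k, toe=flesh_toe)),
        strike=(1, strike_node),
        contact_nodes=contact_nodes,
        impactor_speed=rig.speed,
        impactor_mass=rig.impactor_mass,
        springs=springs,
        shear_ligs=shear_ligs,
        rot_ligs=rot_ligs,
        rot_springs=[RotSpring(beam_a=0, beam_b=1, k=kd["capsule_rotation"])],
        moment_node=(0, n_nodes - 2),
        face_halfwidth=rig.foam.depth / 2.0,
    )
    return sys.run(t_end, dt=dt)


# ---------------------------------------------------------------------------
# Generic entry points
# ---------------------------------------------------------------------------

def explicit_integrate(model: BeamModel, rig: RigSpec, t_end: float,
                       dt: float | None = None,
                       pad: SoftPad | None = None) -> TimeHistory:
    """Run a prebuilt single-beam model under a rig's impactor loading
    (three-point style: mid-shaft strike through a soft pad)."""
    mid = (model.n_nodes - 1) // 2
    strike = int(round(rig.strike_fraction * (model.n_nodes - 1)))
    sys = ExplicitSystem(
        beams=[model],
        pad=pad or SoftPad(),
        strike=(0, strike if strike else mid),
        impactor_speed=rig.speed,
        impactor_mass=None if rig.kind == "three_point" else rig.impactor_mass,
    )
    return sys.run(t_end, dt=dt)


def static_center_deflection(
    model: BeamModel, force: float, t_settle: float = 60.0,
    damping: float = 0.6, dt: float | None = None,
) -> float:
    """Quasi-static mid-span deflection under a constant center load (N),
    obtained by dynamic relaxation of the explicit solver."""
    mid = (model.n_nodes - 1) // 2
    sys = ExplicitSystem(
        beams=[model],
        point_loads=[(0, mid, force)],
        damping=damping,
    )
    sys.run(t_settle, dt=dt, energy_tol=1.0)
    return float(model.w[mid])


def simulate(rig: RigSpec, age: float, segment: str = "thigh", **kw) -> TimeHistory:
    """Dispatch a rig specification to its simulator."""
    if rig.kind == "three_point":
        return simulate_three_point(segment, age, speed=rig.speed, **kw)
    if rig.kind == "four_point_knee":
        return simulate_four_point_knee(age, rate=rig.angular_rate, **kw)
    if rig.kind == "limb_bending":
        return simulate_limb(age, "bending", rig=rig, **kw)
    if rig.kind == "limb_shear":
        return simulate_limb(age, "shear", rig=rig, **kw)
    raise DomainError(f"unknown rig kind {rig.kind!r}")
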