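"""One-dimensional material laws for the beam and joint simulators.

Cortical bone is bilinear elastoplastic with Cowper–Symonds rate scaling of
the yield plateau and brittle failure at a strain limit ("element deletion":
a failed fiber carries zero stress forever).  Cancellous bone is elastic–
perfectly-plastic with a fixed 13.4 % failure strain.  Knee ligaments follow
the standard crimped-collagen fiber law: zero stress in compression, an
exponential toe region while fibers straighten, then a linear region with
the straightened-fiber modulus C5; rupture zeroes the stress permanently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GeometryError
from .materials import (
    CancellousParams,
    CorticalParams,
    RateScalingParams,
    rate_factor,
)

__all__ = [
    "BoneStressState",
    "cortical_update",
    "cancellous_update",
    "bilinear_update_arrays",
    "LigamentFiberLaw",
    "fiber_stress",
    "ligament_law_for_age",
    "LIGAMENT_LAW_YOUNG",
    "LIGAMENT_LAW_ELDERLY",
    "FoamPad",
    "foam_force",
]


@dataclass
class BoneStressState:
    """Stress point of a single bone fiber."""

    total_strain: float = 0.0
    stress: float = 0.0          # MPa
    plastic_strain: float = 0.0  # signed
    accumulated_plastic: float = 0.0
    failed: bool = False


def bilinear_update_arrays(
    strain_new,
    plastic_strain,
    accumulated_plastic,
    failed,
    elastic_modulus_mpa,
    yield_stress,
    tangent_modulus,
    failure_strain,
    rate_scale=1.0,
):
    """Vectorised return-mapping for bilinear 1D plasticity with failure.

    All array arguments broadcast together.  ``rate_scale`` multiplies the
    yield stress only (Cowper–Symonds); the elastic modulus and the plastic
    hardening modulus are rate-independent, so the unloading slope is always
    the elastic modulus.  Returns ``(stress, plastic_strain,
    accumulated_plastic, failed)`` as new arrays.
    """
    eps = np.asarray(strain_new, dtype=float)
    ep = np.array(plastic_strain, dtype=float, copy=True)
    acc = np.array(accumulated_plastic, dtype=float, copy=True)
    dead = np.array(failed, dtype=bool, copy=True)
    E = np.asarray(elastic_modulus_mpa, dtype=float)
    Et = np.asarray(tangent_modulus, dtype=float)
    # plastic (hardening) modulus from the total-strain tangent
    H = np.where(Et > 0, E * Et / np.maximum(E - Et, 1e-12), 0.0)

    trial = E * (eps - ep)
    sig_y = np.asarray(yield_stress, dtype=float) * np.asarray(rate_scale, dtype=float)
    flow = sig_y + H * acc
    over = np.abs(trial) - flow
    yielding = over > 0.0
    dgamma = np.where(yielding, over / (E + H), 0.0)
    sgn = np.sign(trial)
    stress = trial - E * dgamma * sgn
    ep = ep + dgamma * sgn
    acc = acc + dgamma

    dead = dead | (np.abs(eps) >= np.asarray(failure_strain, dtype=float))
    stress = np.where(dead, 0.0, stress)
    return stress, ep, acc, dead


def _scalar_update(
    state: BoneStressState,
    strain_increment: float,
    E_mpa: float,
    yield_stress: float,
    tangent: float,
    failure_strain: float,
    rate_scale: float,
) -> BoneStressState:
    if not math.isfinite(strain_increment):
        raise DomainError(f"non-finite strain increment {strain_increment}")
    eps = state.total_strain + strain_increment
    s, ep, acc, dead = bilinear_update_arrays(
        eps,
        state.plastic_strain,
        state.accumulated_plastic,
        state.failed,
        E_mpa,
        yield_stress,
        tangent,
        failure_strain,
        rate_scale,
    )
    return BoneStressState(
        total_strain=eps,
        stress=float(s),
        plastic_strain=float(ep),
        accumulated_plastic=float(acc),
        failed=bool(dead),
    )


def cortical_update(
    state: BoneStressState,
    strain_increment: float,
    params: CorticalParams,
    strain_rate: float = 0.0,
    rate_params: RateScalingParams | None = None,
) -> BoneStressState:
    """Advance a cortical fiber by one strain increment.

    The yield plateau is scaled by the Cowper–Symonds factor at the given
    strain rate; reaching the failure strain fails the fiber permanently.
    """
    scale = rate_factor(abs(strain_rate), rate_params)
    return _scalar_update(
        state,
        strain_increment,
        params.elastic_modulus * 1000.0,  # GPa -> MPa
        params.yield_stress,
        params.tangent_modulus,
        params.failure_strain,
        scale,
    )


def cancellous_update(
    state: BoneStressState,
    strain_increment: float,
    params: CancellousParams,
) -> BoneStressState:
    """Advance a cancellous fiber: elastic–perfectly-plastic, no rate effect."""
    return _scalar_update(
        state,
        strain_increment,
        params.elastic_modulus,
        params.yield_stress,
        0.0,
        params.failure_strain,
        1.0,
    )


@dataclass(frozen=True)
class LigamentFiberLaw:
    """Crimped-collagen ligament fiber law.

    ``C3`` (MPa) scales and ``C4`` (dimensionless) controls the rise of the
    exponential toe stresses; ``C5`` (MPa) is the modulus of straightened
    collagen fibers.  ``C1`` (MPa, first Mooney–Rivlin constant) and the
    bulk modulus describe the ground-substance matrix, folded into a small
    parallel linear stiffness in 1D.  The toe-to-linear transition stretch
    is fixed by C1-continuity: ``lambda* = 1 + ln(C5/(C3*C4))/C4``.
    """

    C1: float            # MPa
    C3: float            # MPa
    C4: float            # dimensionless
    C5: float            # MPa
    bulk_modulus: float  # GPa
    failure_strain: float
    density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        if min(self.C3, self.C4, self.C5) <= 0:
            raise DomainError("C3, C4, C5 must be positive")
        if self.C5 <= self.C3 * self.C4:
            raise DomainError(
                "C5 must exceed C3*C4 for a transition stretch above 1"
            )
        if self.failure_strain <= 0:
            raise DomainError("failure strain must be positive")

    @property
    def lambda_star(self) -> float:
        """Stretch at which collagen fibers are fully straightened."""
        return 1.0 + math.log(self.C5 / (self.C3 * self.C4)) / self.C4

    @property
    def matrix_stiffness(self) -> float:
        """Small parallel linear matrix stiffness (MPa per unit stretch)."""
        return 2.0 * self.C1


#: Published ligament columns for the 30- and 70-year-old knees.
LIGAMENT_LAW_YOUNG = LigamentFiberLaw(
    C1=34.29, C3=1.54, C4=152.85, C5=836.42, bulk_modulus=4.31, failure_strain=0.45
)
LIGAMENT_LAW_ELDERLY = LigamentFiberLaw(
    C1=22.13, C3=0.6, C4=147.8, C5=695.66, bulk_modulus=3.5, failure_strain=0.263
)


def ligament_law_for_age(age: float) -> LigamentFiberLaw:
    """Linear per-parameter interpolation between the age-30 and age-70
    ligament columns, clamped outside [30, 70]."""
    t = min(max((float(age) - 30.0) / 40.0, 0.0), 1.0)
    y, e = LIGAMENT_LAW_YOUNG, LIGAMENT_LAW_ELDERLY

    def lerp(a: float, b: float) -> float:
        return a + t * (b - a)

    return LigamentFiberLaw(
        C1=lerp(y.C1, e.C1),
        C3=lerp(y.C3, e.C3),
        C4=lerp(y.C4, e.C4),
        C5=lerp(y.C5, e.C5),
        bulk_modulus=lerp(y.bulk_modulus, e.bulk_modulus),
        failure_strain=lerp(y.failure_strain, e.failure_strain),
    )


def fiber_stress(stretch, law: LigamentFiberLaw, include_matrix: bool = False):
    """Fiber Cauchy-like stress (MPa) at stretch ``lambda``.

    Zero for ``lambda <= 1`` (fibers cannot push); exponential toe
    ``C3*(exp(C4*(lambda-1)) - 1)`` up to the straightening stretch; linear
    with slope ``C5`` beyond, joined with value and slope continuity.  Once
    the engineering strain ``lambda - 1`` reaches the failure strain the
    stress is zero (rupture).  Vectorised over ``stretch``.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("stretch must be positive")
    ls = law.lambda_star
    # stress at the transition, from the toe branch: C5/C4 - C3
    sig_star = law.C5 / law.C4 - law.C3
    toe = law.C3 * (np.expm1(law.C4 * (lam - 1.0)))
    lin = sig_star + law.C5 * (lam - ls)
    sig = np.where(lam <= 1.0, 0.0, np.where(lam < ls, toe, lin))
    if include_matrix:
        sig = sig + np.where(lam > 1.0, law.matrix_stiffness * (lam - 1.0), 0.0)
    sig = np.where(lam - 1.0 >= law.failure_strain, 0.0, sig)
    if np.isscalar(stretch) or np.ndim(stretch) == 0:
        return float(sig)
    return sig


_DEFAULT_FOAM_CURVE = (
    (0.0, 0.0),
    (0.05, 0.5),   # elastic toe up to the crush plateau
    (0.80, 1.40),  # mildly hardening crush plateau
    (0.95, 12.0),  # densification
)


@dataclass(frozen=True)
class FoamPad:
    """Crushable foam pad wrapped on the impactor face.

    ``curve`` maps crush strain (depth/thickness) to crush stress in MPa and
    must be monotone nondecreasing; the pad is treated as nonlinear elastic
    for the energy audit (unloading retraces the curve).
    """

    width: float = 100.0      # mm
    depth: float = 120.0      # mm
    thickness: float = 50.0   # mm
    curve: tuple[tuple[float, float], ...] = _DEFAULT_FOAM_CURVE

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.width <= 0 or self.depth <= 0:
            raise GeometryError("pad dimensions must be positive")
        strains = [s for s, _ in self.curve]
        stresses = [p for _, p in self.curve]
        if any(b < a for a, b in zip(strains, strains[1:])) or any(
            b < a for a, b in zip(stresses, stresses[1:])
        ):
            raise DomainError("foam curve must be monotone nondecreasing")

    @property
    def area(self) -> float:
        return self.width * self.depth  # mm^2

    def stress_at(self, strain: float) -> float:
        s = np.array([p[0] for p in self.curve])
        v = np.array([p[1] for p in self.curve])
        return float(np.interp(strain, s, v))

    def energy_at(self, crush_depth: float) -> float:
        """Stored energy in N*mm at a crush depth (trapezoid on the curve)."""
        if crush_depth <= 0:
            return 0.0
        strain = crush_depth / self.thickness
        s = np.array([p[0] for p in self.curve])
        v = np.array([p[1] for p in self.curve])
        grid = np.linspace(0.0, strain, 200)
        stress = np.interp(grid, s, v)
        return float(np.trapezoid(stress, grid) * self.thickness * self.area)


def foam_force(crush_depth: float, pad: FoamPad) -> float:
    """Contact force in kN transmitted through the pad at a crush depth (mm)."""
    if crush_depth < 0:
        raise DomainError("crush depth must be nonnegative")
    if crush_depth >= pad.thickness:
        raise DomainError(
            f"crush depth {crush_depth} mm reaches pad densification "
            f"(thickness {pad.thickness} mm)"
        )
    stress = pad.stress_at(crush_depth / pad.thickness)
    return stress * pad.area / 1000.0  # MPa * mm^2 = N -> kN
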