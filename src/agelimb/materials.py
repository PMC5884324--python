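"""Age regressions for long-bone material properties.

Adult male lower-extremity bone properties change markedly with age:
cancellous (trabecular) bone stiffness and strength rise until about age 40
and decline afterwards, while cortical stiffness, strength and ductility
decline linearly throughout adulthood.  This module evaluates the published
regressions for those trends, applies per-bone site multipliers, applies
Cowper–Symonds strain-rate scaling of the yield stress, and assembles
complete per-age material tables for the femur, tibia and fibula.

Units follow explicit-dynamics convention: stresses in MPa, cortical elastic
modulus in GPa (cancellous in MPa), densities in kg/m^3, strains as
dimensionless fractions, strain rate in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

from .errors import DomainError

if TYPE_CHECKING:  # pragma: no cover
    from .constitutive import LigamentFiberLaw

AGE_MIN = 20.0
AGE_MAX = 90.0

#: Cowper–Symonds strain-rate constants for cortical bone.
COWPER_SYMONDS_C = 360.5  # 1/s
COWPER_SYMONDS_P = 3.6

CORTICAL_DENSITY = 2000.0  # kg/m^3
CORTICAL_POISSON = 0.3
CANCELLOUS_DENSITY = 1000.0  # kg/m^3
CANCELLOUS_POISSON = 0.45
#: Ultimate (failure) strain of cancellous bone, age-independent.
CANCELLOUS_FAILURE_STRAIN = 0.134

#: Plastic tangent modulus of cortical bone, as a fraction of the
#: age-specific elastic modulus.  The plastic slope is taken as
#: age-independent in relative terms; no absolute value is published.
CORTICAL_TANGENT_FRACTION = 0.05

BONES = ("femur", "tibia", "fibula")
TISSUES = ("cortical", "cancellous")

#: Table-2 femoral cancellous elderly elastic modulus that contradicts the
#: quadratic regression's post-40 decline; exposed for explicit override only.
TABLE2_FEMORAL_CANCELLOUS_E_70 = 816.4  # MPa
#: Table-2 femoral cortical yield stress at age 30 that disagrees with the
#: linear ultimate-stress regression (which gives 115.2 MPa); informational.
TABLE2_FEMORAL_CORTICAL_YIELD_30 = 100.22  # MPa


def _check_age(age: float) -> float:
    age = float(age)
    if not (AGE_MIN <= age <= AGE_MAX):
        raise DomainError(
            f"age {age} years outside the validated range "
            f"[{AGE_MIN:g}, {AGE_MAX:g}]"
        )
    return age


def cancellous_base(age: float) -> tuple[float, float]:
    """Quadratic age regressions for cancellous bone (tibial reference site).

    Parameters
    ----------
    age : float
        Age in years, within [20, 90].

    Returns
    -------
    (elastic_modulus, ultimate_stress) : tuple of float
        Elastic modulus in MPa and ultimate (= yield plateau) stress in MPa.
        Both are concave quadratics peaking near age 39–40.
    """
    age = _check_age(age)
    e = 473.3 + 14.99 * age - 0.19 * age * age
    s = 8.94 + 0.13 * age - 0.002 * age * age
    return e, s


def cortical_base(age: float) -> tuple[float, float, float]:
    """Linear age regressions for cortical bone (femoral reference site).

    Returns
    -------
    (elastic_modulus, ultimate_stress, failure_strain) : tuple of float
        Elastic modulus in GPa, ultimate stress in MPa, failure strain as a
        dimensionless fraction (the underlying regression is in percent).
        All three decrease strictly with age.
    """
    age = _check_age(age)
    e = 18.01 - 0.059 * age          # GPa
    s = 130.8 - 0.52 * age           # MPa
    eps = (4.23 - 0.033 * age) / 100.0  # percent -> fraction
    return e, s, eps


@dataclass(frozen=True)
class RateScalingParams:
    """Cowper–Symonds constants: yield multiplier 1 + (rate/C)^(1/P)."""

    C: float = COWPER_SYMONDS_C  # 1/s
    P: float = COWPER_SYMONDS_P

    def __post_init__(self) -> None:
        if self.C <= 0 or self.P <= 0:
            raise DomainError("Cowper-Symonds C and P must be positive")


def rate_factor(strain_rate: float, params: RateScalingParams | None = None) -> float:
    """Cowper–Symonds dynamic yield-stress multiplier ``1 + (rate/C)**(1/P)``.

    Equals 1 at zero rate and exactly 2 at ``rate == C``; monotone
    nondecreasing and unbounded in the strain rate.
    """
    if params is None:
        params = RateScalingParams()
    if strain_rate < 0:
        raise DomainError(f"strain rate must be nonnegative, got {strain_rate}")
    if strain_rate == 0:
        return 1.0
    return 1.0 + (strain_rate / params.C) ** (1.0 / params.P)


@dataclass(frozen=True)
class CorticalParams:
    """Cortical bone bilinear elastoplastic parameters for one bone and age."""

    elastic_modulus: float  # GPa
    yield_stress: float     # MPa; ultimate stress used as the yield plateau
    failure_strain: float   # fraction
    tangent_modulus: float  # MPa
    density: float = CORTICAL_DENSITY  # kg/m^3
    poisson: float = CORTICAL_POISSON

    def __post_init__(self) -> None:
        if min(self.elastic_modulus, self.yield_stress, self.failure_strain,
               self.tangent_modulus, self.density) <= 0:
            raise DomainError("cortical parameters must be positive")
        if self.failure_strain >= 0.1:
            raise DomainError("cortical failure strain must be below 0.1")
        if self.tangent_modulus >= self.elastic_modulus * 1000.0:
            raise DomainError("tangent modulus must be below the elastic modulus")


@dataclass(frozen=True)
class CancellousParams:
    """Cancellous bone elastic–perfectly-plastic parameters."""

    elastic_modulus: float  # MPa
    yield_stress: float     # MPa (= ultimate stress; flat plateau)
    failure_strain: float = CANCELLOUS_FAILURE_STRAIN
    density: float = CANCELLOUS_DENSITY  # kg/m^3
    poisson: float = CANCELLOUS_POISSON

    def __post_init__(self) -> None:
        if min(self.elastic_modulus, self.yield_stress, self.density) <= 0:
            raise DomainError("cancellous parameters must be positive")


@dataclass(frozen=True)
class SiteScale:
    """Multiplicative adjustment from the regression's reference site."""

    e_scale: float = 1.0
    stress_scale: float = 1.0
    strain_scale: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.e_scale, self.stress_scale, self.strain_scale):
            if not (0.5 < v < 1.5):
                raise DomainError(f"site scale {v} outside the plausible band (0.5, 1.5)")


def _default_site_multipliers() -> dict[tuple[str, str], SiteScale]:
    # Reference sites: the cortical regressions reproduce the femoral column,
    # the cancellous regressions the tibial column.  Tibial cortical ratios
    # are the published young/elderly column ratios averaged; fibula data are
    # unavailable and the fibula is taken identical to the tibia.
    tib_cort = SiteScale(e_scale=1.13, stress_scale=1.20, strain_scale=1.05)
    fem_canc = SiteScale(stress_scale=1.20)
    table = {
        ("femur", "cortical"): SiteScale(),
        ("tibia", "cortical"): tib_cort,
        ("fibula", "cortical"): tib_cort,
        ("femur", "cancellous"): fem_canc,
        ("tibia", "cancellous"): SiteScale(),
        ("fibula", "cancellous"): SiteScale(),
    }
    return table


@dataclass(frozen=True)
class SiteMultipliers:
    """Per-(bone, tissue) multiplicative site adjustments.

    Invariant: fibula multipliers equal tibia multipliers.
    """

    table: dict[tuple[str, str], SiteScale] = field(
        default_factory=_default_site_multipliers
    )

    def get(self, bone: str, tissue: str) -> SiteScale:
        key = (bone, tissue)
        if key not in self.table:
            raise DomainError(
                f"unknown bone/tissue pair {bone!r}/{tissue!r}; "
                f"bones: {BONES}, tissues: {TISSUES}"
            )
        return self.table[key]


DEFAULT_SITE_MULTIPLIERS = SiteMultipliers()


def site_adjust(
    params: CorticalParams | CancellousParams,
    bone: str,
    tissue: str,
    multipliers: SiteMultipliers | None = None,
):
    """Scale reference-site parameters to another bone of the lower limb."""
    mult = (multipliers or DEFAULT_SITE_MULTIPLIERS).get(bone, tissue)
    if isinstance(params, CorticalParams):
        return replace(
            params,
            elastic_modulus=params.elastic_modulus * mult.e_scale,
            yield_stress=params.yield_stress * mult.stress_scale,
            failure_strain=params.failure_strain * mult.strain_scale,
            tangent_modulus=params.tangent_modulus * mult.e_scale,
        )
    if isinstance(params, CancellousParams):
        return replace(
            params,
            elastic_modulus=params.elastic_modulus * mult.e_scale,
            yield_stress=params.yield_stress * mult.stress_scale,
        )
    raise DomainError(f"unsupported parameter type {type(params).__name__}")


def cortical_params(
    age: float,
    bone: str = "femur",
    multipliers: SiteMultipliers | None = None,
    tangent_fraction: float = CORTICAL_TANGENT_FRACTION,
) -> CorticalParams:
    """Complete cortical parameter set for one bone at one age."""
    e, s, eps = cortical_base(age)
    base = CorticalParams(
        elastic_modulus=e,
        yield_stress=s,
        failure_strain=eps,
        tangent_modulus=tangent_fraction * e * 1000.0,  # GPa -> MPa
    )
    return site_adjust(base, bone, "cortical", multipliers)


def cancellous_params(
    age: float,
    bone: str = "tibia",
    multipliers: SiteMultipliers | None = None,
) -> CancellousParams:
    """Complete cancellous parameter set for one bone at one age."""
    e, s = cancellous_base(age)
    base = CancellousParams(elastic_modulus=e, yield_stress=s)
    return site_adjust(base, bone, "cancellous", multipliers)


@dataclass(frozen=True)
class AgeMaterialSet:
    """Every bone/ligament material parameter for a single age."""

    age: float
    cortical: dict[str, CorticalParams]
    cancellous: dict[str, CancellousParams]
    ligament: "LigamentFiberLaw"
    rate: RateScalingParams = field(default_factory=RateScalingParams)


def material_table(
    age: float,
    multipliers: SiteMultipliers | None = None,
    tangent_fraction: float = CORTICAL_TANGENT_FRACTION,
) -> AgeMaterialSet:
    """Assemble the full per-age material table for the three long bones.

    Deterministic; raises :class:`~agelimb.errors.DomainError` outside
    age 20–90.  The ligament law interpolates linearly between the
    published 30- and 70-year-old columns (clamped outside).
    """
    from .constitutive import ligament_law_for_age

    age = _check_age(age)
    cort = {b: cortical_params(age, b, multipliers, tangent_fraction) for b in BONES}
    canc = {b: cancellous_params(age, b, multipliers) for b in BONES}
    return AgeMaterialSet(
        age=age, cortical=cort, cancellous=canc, ligament=ligament_law_for_age(age)
    )


def cancellous_peak_age(lo: float = 20.0, hi: float = 80.0, step: float = 0.1) -> float:
    """Grid argmax of the cancellous elastic-modulus regression on [lo, hi]."""
    best_age, best_e = lo, -math.inf
    n = int(round((hi - lo) / step))
    for i in range(n + 1):
        a = lo + i * step
        e, _ = cancellous_base(a)
        if e > best_e:
            best_age, best_e = a, e
    return best_age
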