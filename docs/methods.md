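# Methods

`agelimb` models how the human lower extremity's injury tolerance changes
with adult age, for pedestrian-impact applications.  It combines three
ingredients — age regressions for bone and ligament material properties,
age scaling of long-bone cross-section geometry, and simplified
explicit-dynamics simulations of the standard cadaver validation load
cases — and reports fracture and ligament-rupture events.

## 1. Material aging model

### Cancellous (trabecular) bone

Quasi-static compression data across adulthood are summarised by concave
quadratics in age (years):

    E  [MPa] = 473.3 + 14.99 a − 0.19 a²
    σu [MPa] = 8.94 + 0.13 a − 0.002 a²

Both peak near age 39–40 and decline afterwards.  Cancellous bone is
modelled elastic–perfectly-plastic (the plateau stress equals the
ultimate stress, like a metal foam) with an age-independent failure
strain of 13.4 %.  Density 1000 kg/m³, ν = 0.45.

### Cortical bone

Linear declines with age:

    E  [GPa] = 18.01 − 0.059 a
    σu [MPa] = 130.8 − 0.52 a
    εf [%]   = 4.23 − 0.033 a

Cortical bone is bilinear elastoplastic: the ultimate stress serves as
the yield plateau, the plastic tangent modulus defaults to 5 % of the
age-specific elastic modulus (the plastic slope is reported not to
change with age but no value is published; the 5 % fraction is a
configurable default), and reaching the failure strain deletes the
material point (stress zero permanently) — the fracture mechanism.
Density 2000 kg/m³, ν = 0.3.

Rate dependence follows Cowper–Symonds: the yield stress is multiplied
by `1 + (ε̇/C)^(1/P)` with C = 360.5 s⁻¹ and P = 3.6.  Only the yield
scales; the elastic modulus (and so the unloading slope) is rate
independent.  Rate scaling is applied to cortical bone only: whether it
applies to cancellous bone is unstated in the source data, and the
conservative default is no.

### Site multipliers

The cortical regressions reproduce the femoral column of the reference
table and the cancellous regressions the tibial column.  Other sites are
reached by multiplicative adjustments estimated from the ratios of the
published young/elderly columns (tibial cortical: stiffness ×1.13,
strength ×1.20, failure strain ×1.05; femoral cancellous strength
×1.20), with the fibula set identical to the tibia (no age-resolved
fibula data exist).  All multipliers are configurable.

Two cells of the published table are internally inconsistent with the
stated regressions and are treated as suspected errata: the femoral
cortical yield stress at age 30 (printed 100.22 MPa vs the regression's
115.2 MPa) and the elderly femoral cancellous modulus (printed
816.4 MPa, which contradicts the quadratic's post-40 decline).  The
regressions are authoritative by default; the printed values remain
accessible as named constants.

### Knee ligaments

Ligaments use the transversely isotropic crimped-collagen law: zero
stress in compression, an exponential toe region
`σ = C3 (exp(C4 (λ−1)) − 1)` while fibers straighten, then a linear
region with the straightened-fiber modulus C5.  The transition stretch
λ* is not published; it is fixed by requiring value *and* slope
continuity, giving the closed form `λ* = 1 + ln(C5/(C3 C4))/C4` with no
extra free parameter.  The ground-substance matrix (C1, bulk modulus) is
folded into a small parallel linear stiffness (2·C1 per unit stretch) in
the 1D elements; a full 3D Mooney–Rivlin split is out of scope.  Rupture
occurs when the fiber engineering strain reaches the failure strain
(0.45 young, 0.263 elderly) and permanently zeroes the element force.
Parameters between ages 30 and 70 interpolate linearly per parameter and
clamp outside that range, since only the two endpoint columns are
published.

## 2. Geometric aging model

An idealised annular shaft cross-section is described by the periosteal
diameter D_P and medullary diameter D_M, with TA = πD_P²/4,
MA = πD_M²/4, CA = TA − MA, and the annulus second moment
I = π(D_P⁴ − D_M⁴)/64.

Aging is anchored by a per-bone, per-station table of total percent
increases of D_P and D_M for a 70-year-old relative to the 26-year-old
baseline, at the five shaft stations 20/35/50/65/80 % from the proximal
end.  Between the baseline and the anchor the increase is spread
linearly in (age − 26) — i.e. the per-decade growth rate is taken
constant, because the anchor is the only tabulated quantity — and the
same rate extrapolates to age 90.  Medullary expansion outpaces
periosteal expansion at every femur/tibia station, so aging thins the
cortex (CA falls) while TA grows.

Because the baseline geometry the growth data refer to is proprietary
and unpublished, the package ships a clearly labelled *synthetic*
26-year-old baseline with literature-typical shaft diameters (femur
mid-shaft D_P = 28 mm, D_M = 14 mm, etc.).  The baseline
medullary-to-periosteal ratios were chosen so that the growth table
implies cortical thinning at every station, as it does in the population
data it summarises; all diameters are overridable.

### Mesh morphing

The reference workflow morphs a finite-element mesh with interactive
handles; here that is re-implemented as axis-based two-layer radial
scaling: each node is projected onto the shaft axis (supplied, or fit as
the dominant principal axis), classified as periosteal or endosteal by
comparing its radius with the baseline layer radii at that axial
fraction (explicit labels can be supplied instead), and its radial
coordinate is multiplied by the axially interpolated r_P or r_M.  Axial
coordinates and topology are untouched; ratios between stations
interpolate piecewise-linearly and clamp beyond the end stations.  A
node whose radius sits more than 35 % of the local layer gap away from
both layers is ambiguous and raises an error rather than being guessed.

## 3. Explicit beam simulator

Each long bone is a planar finite-difference beam: nodes carry lateral
displacement, interior nodes own a fiber discretisation of their annular
cross-section (16 cortical strips around 8 cancellous strips).  Each
strip's exact area and second moment are integrated at setup, and the
fiber lever arm is chosen as sqrt(I_strip/A_strip) so the elastic
section stiffness is reproduced essentially exactly.  Fiber strains
follow from the discrete curvature; fiber stresses from the 1D laws
above; the section moment from the fiber sum; and the nodal internal
force from the second difference of the moment.  Failed fibers drop out
of the sum, so a fully failed section degenerates to a hinge.

Integration is central-difference explicit with the step set to 0.9× the
stability limit (beam flexural modes, contact stiffness and ligament
stiffness all considered).  The per-step strain-rate estimate feeding
the Cowper–Symonds scale is low-pass filtered with a 0.2 ms time
constant: the raw estimate carries near-Nyquist element oscillation and
would make the dynamic strength depend on the step size.

A running energy audit tracks external work (or initial impactor kinetic
energy), kinetic energy, fiber internal work, ligament work, spring
potentials, pad potential and damping dissipation; the solver aborts if
the imbalance exceeds 5 % (the rigs stay below 1 %).  Contact pads are
treated as nonlinear elastic (unloading retraces the curve) so the audit
has an exact potential; crush dissipation is not separated out.

Outputs are decimated to a 0.1 ms grid.  Events record the first
failure per component and kind (cortical fracture, cancellous failure,
ligament rupture) with the axial fraction of the failing section.
Everything is deterministic for a given configuration.

## 4. Validation rigs

The rigs reproduce the standard cadaver load cases at beam fidelity.
Absolute force and displacement magnitudes of 3D cadaver tests are *not*
reproduction targets — the flesh, joints and 3D bone geometry are
deliberately reduced — but the young/elderly orderings and the response
shapes are, and those are what the tests assert.  Rig constants below
were chosen once from the test descriptions and anatomical reasoning and
are configuration, not fitted quantities.

**Three-point bending (thigh / calf).**  Potted specimen ends are
pinned; a kinematic impactor advances at 1.5 m/s into a lumped
soft-tissue pad (quadratic toe then linear, 350 N/mm with a 12–15 mm
toe), so the force rises slowly during flesh compression and sharply
once the bone loads.  In the calf, the impactor strikes the fibula,
which transmits to the tibia through a compliant interosseous/soft-
tissue coupling spring (200 N/mm).  The compliant coupling lets the
directly struck slender fibula deflect and strain ahead of the tibia,
which is what makes the fibula fracture first, followed by continued
loading of the tibia — the observed failure sequence.  A rigid coupling
would lock the deflections and invert the order.

**Four-point knee bending.**  The extension bars prescribe the valgus
opening angle at 1 deg/ms.  Valgus rotation opens the medial side about
the lateral condyle contact, so the MCL lever is close to the full knee
width: the MCL is a 3-fiber bundle with an 80 mm lever, a 60 mm
functional reference length and a 9 mm² effective load-bearing area, in
parallel with a small elastic capsule (0.5 N·m/deg).  The moment rises
monotonically, peaks as the bundle starts to rupture, then collapses.
The ligament law is rate-independent, so the moment–angle curve equals
the quasi-static curve traversed at the prescribed rate.

**Whole-limb bending and shear.**  Femur and tibia beams are joined by
the knee: MCL/LCL bundles resist relative rotation, ACL/PCL fibers
resist relative shear (effective areas 6–9 mm², sized so rupture forces
land in the 2–3 kN range reported for isolated-ligament tests), plus a
weak capsule.  The femur is pinned at the hip, restrained near the knee
by a 600 N/mm fixture-plate spring, and both bones carry the 400 N
standing preload as a uniform axial strain offset.  A free 6.25 kg
impactor at 40 km/h loads the limb through the 100×120×50 mm foam pad in
series with local flesh (400 N/mm, 8 mm toe); the 120 mm face is spread
over the nodes it covers, and in the shear case it spans the joint line,
loading the proximal tibia and distal femur together.  The foam crush
curve defaults to a 0.5 MPa plateau that hardens mildly to 1.4 MPa by
80 % strain before densification: perfectly flat plateaus make the
contact force insensitive to the structure behind the pad, while the
mild hardening keeps the transmitted force monotone in the structural
resistance — which is also how real impact foams behave.

Lumped flesh masses: thigh 7.0 kg, calf 2.8 kg (tibia) + 0.7 kg
(fibula), foot 1.0 kg.

## 5. Ligament calibration

`simulate_tension` maps a fiber law through a specimen geometry
(reference length 30 mm, effective area 6 mm², giving young peak forces
near the ~2.2 kN scale of femur–ACL–tibia tests) to a force–displacement
curve including the rupture drop.  `inverse_fit` recovers
(C3, C4, C5) by bounded least squares on the pre-rupture samples in
log-parameter space, multi-started from a seeded Latin-hypercube over
the bounds; the failure strain is identified directly from the rupture
drop.  Because the source experiments' raw curves are not tabulated,
calibration is exercised on synthetic curves generated from the
published endpoint parameter sets — parameter recovery (exactness on
noiseless curves, robustness under 2 % multiplicative noise) is the
verifiable surface.

## 6. What the synthetic data do and do not show

The synthetic baseline bones, tube meshes and tension curves emulate the
*structure* of the real inputs (five-station shaft geometry, two-layer
cortical/cancellous sections, toe-then-linear-then-rupture tension
curves), so passing tests demonstrate that the aging regressions,
geometric scaling, constitutive laws, solver and calibration machinery
are internally consistent and reproduce the published anchors and
orderings.  They do not demonstrate biofidelity of absolute responses:
real bones are non-circular and non-prismatic, real flesh is a
continuum, the knee has menisci and condyle contact, and real
experimental curves carry structured (not multiplicative white) noise.

## 7. Problem sizes and numerical defaults

Default discretisations — 33 nodes per bone for component rigs, 25 per
bone for the two-bone limb rigs, 0.1 ms output, stability-limited step
(~5–15 µs) — were chosen at the point where halving the step changes
peak forces by <1 % and doubling the node count changes peak force and
fracture time by <3 %, which the test suite verifies directly.  A full
rig simulation takes well under a second, so the whole young/elderly rig
matrix runs in a few seconds.

## 8. Known limitations

- Planar bending/shear only; no torsion, no axial wave propagation, no
  3D kinematics or muscle activity.
- Fracture is strain-driven fiber deletion; no fracture mechanics,
  fragmentation or comminution.
- The knee is a planar joint of fiber bundles; no menisci, condyle
  contact surfaces or patella.
- Site multipliers and the 26-year-old baseline diameters are estimated,
  not measured; both are configuration.
- Sex effects, pediatric ages, epiphyseal geometry and bone-density
  imaging inputs are out of scope.
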