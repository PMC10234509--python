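# Methods

This note documents the model, the numerical choices, and what the
package's synthetic test problems do and do not establish.

## Constitutive model

Muscle is a quasi-incompressible, transversely isotropic hyperelastic
solid.  The strain energy splits into an isotropic exponential matrix
term `W_I = c (exp(b(Ī₁−3)) − 1)`, a quadratic volumetric penalty
`W_V = (1/D)(J−1)²`, and a fiber term whose stress is the sum of the
parallel-elastic (PE) stress and the common stress of the series
contractile/series-elastic (CE/SEE) pair.  All fiber rheology is driven
by the *modified* fiber stretch λ̄_f = J^(−1/3) λ_f: for the default
compressibility D the difference from the total stretch is below 0.1%,
and using the isochoric measure keeps the fiber response strictly
volume-independent, consistent with the energy split.

Element responses:

* PE: `σ_PE = σ₀ A (λ̄_f − 1)²` in tension, slack otherwise.
* SEE: `σ_SEE = β (exp(α(λ_s − 1)) − 1)`, with the exact incremental
  update `σ_SEE(t+Δt) = e^{αΔλ_s}(σ_SEE(t)+β) − β`.  This functional
  form is the unique parse for which the incremental identity holds
  exactly and σ_SEE(1) = 0; a unit test asserts the identity to 1e−12.
* CE: `σ_CE = σ₀ f_λ f_v f_t`.  f_λ is the standard piecewise parabola
  family in r = λ̄_f/λ_opt with breakpoints 0.4/0.6/1.4/1.6 and branch
  values 0/0.36/0.36/0 at the joints.  f_v has the hyperbolic
  concentric branch (1−r_m)/(1+k_c r_m) in r_m = λ̇_m/λ̇_m,min (clamped
  to 0 beyond maximal shortening) and the eccentric branch
  `d − (d−1)(1+r_m)/(1 − k_c k_e r_m)` — the only bracketing that is 1
  at zero rate, exceeds 1 for lengthening and approaches the finite
  asymptote d + (d−1)/(k_c k_e).  The activation schedule rises from n₁
  toward n₂ after t₀ at exponential rate S and decays back after t₁;
  with S = 50 s⁻¹ a 0.5 s hold reaches full activation to within e^(−25),
  which is why the active elongation protocol holds for 0.5 s before
  pulling.

### Series kinematics and the increment solve

With k the CE-to-SEE rest-length ratio, lengths in series give
`(1+k) λ̄_f = k λ_m + λ_s`.  Equating the incremental SEE stress to the
CE stress yields one scalar equation per increment,
`f(Δλ_s) = (w₂ + w₃Δλ_s)e^{αΔλ_s} − w₄Δλ_s − w₅ = 0`, with coefficient
sets for the concentric and eccentric phases.  The coefficients are
derived here directly from that equality (using
`λ̇_m = (w₁ − Δλ_s)/(kΔt)`, `w₁ = (1+k)λ̄_f(t+Δt) − kλ_m − λ_s`), so the
root of f is *identically* the root of the raw equilibrium residual
within each phase.

The raw residual is strictly monotone in Δλ_s (SEE stress rises, the CE
rate and with it f_v falls), so the root is unique and its phase is
decided a priori by the sign of the residual at the zero-rate point
Δλ_s = w₁: negative means a concentric root (above w₁), positive an
eccentric one (below).  The solver bisects a directional bracket
anchored at w₁ (initial half-width 0.5, doubled up to four times, 80
bisection iterations), with an exact early accept when the state is
already in equilibrium — so a resting, unactivated point returns
Δλ_s = 0 bit-exactly.  If the concentric root would exceed the maximal
shortening rate, the CE transmits nothing and the SEE unloads in closed
form (Δλ_s = ln(β/(β+σ_SEE))/α).  Every accepted step asserts
|σ_CE − σ_SEE| ≤ 1e−9(β + σ₀); an independent dense-grid + bisection
oracle cross-checks the root on 1000 random states in the test suite.
Initialization is stress-free: λ_s = 1, λ_m = λ̄_f(0), σ_SEE = 0.

Note a quirk of the default parameterization: the SEE modulus β = 1 kPa
is soft against σ₀ = 700 kPa, so a fully loaded SEE equilibrates near
λ_s ≈ 1.65 and the CE stretch variable — which feeds only the *rate* in
f_v, since f_λ is a function of the total modified fiber stretch — can
leave [0, 1] at high stress.  This is faithful to the printed law; λ_m
is an internal rheological variable, not a geometric sarcomere length.

All response functions and the increment solver broadcast over numpy
arrays; the FE solver and the isometric sweep advance thousands of
material points per call.

### Stress tensor

The model prescribes only the energy; the tensorial stress follows the
standard quasi-incompressible transversely isotropic treatment: second
Piola–Kirchhoff stress from 2∂W/∂C with deviatoric projection of the
isochoric matrix and fiber terms, pushed forward to Cauchy stress:

    σ = (2/J) W_I′(Ī₁) dev(B̄) + (σ_PE+σ_SEE) (λ̄_f/J) dev(â⊗â) + (2/D)(J−1) I

with B̄ the isochoric left Cauchy–Green tensor and â the current fiber
direction.  Objectivity and agreement with a finite-difference energy
gradient (1e−5 relative on random states) are asserted in tests.

## Default parameters

The packaged defaults are the calibrated rabbit tibialis-anterior set:
D = 5e−9 Pa⁻¹, b = 15, c = 379 Pa, A = 4, σ₀ = 7e5 Pa, α = 10,
β = 1e3 Pa, λ_opt = 1.05, k = 0.3, k_c = 4, k_e = 5, d = 1.45,
λ̇_m,min = −17 s⁻¹, S = 50 s⁻¹.  The activation levels n₁/n₂ are
protocol quantities, not material ones; the defaults n₁ = 0, n₂ = 1
make passive simulations exactly inert and active ones fully recruited.
All internal units are SI; mm-based inputs (cohesive stiffnesses in
N/mm³, separations in mm) are converted at the I/O boundary.

## Homogeneous elongation driver

The uniaxial driver prescribes the axial stretch history
(constant-velocity pull, optional isometric pre-hold) and solves the
lateral stretch by Brent root-finding so both lateral Cauchy stresses
vanish to below 1 Pa; the trial state advance is inside the root solve
because λ̄_f depends on J.  Engineering stress is the axial
first Piola–Kirchhoff component σ_xx λ_lat².  For FE specimens the
reaction force is normalized by the mid-belly cross-section by default,
with the end-cap normalization always reported alongside (which section
the experimental normalization used is not determinable, so both are
computed).  Default step 1e−3 s; halving it changes the final stress by
well under 0.5%.

## Explicit FE solver

Total-Lagrangian linear tetrahedra with one integration point, lumped
mass, central-difference integration, exact enforcement of fixed and
prescribed-velocity boundaries, optional mass-proportional damping and
cohesive pairs.  The stable increment is estimated from the smallest
element's characteristic length and a stiffness dominated by the
volumetric penalty 2/D, safety factor 0.8.  Density defaults to
1060 kg/m³ (typical skeletal muscle).

Quasi-static runs use mass scaling plus a two-phase damping schedule,
and this choice matters at near-incompressibility: the *loading* phase
must be lightly damped (mass-proportional drag ρcν on moving material
otherwise swamps the physical stresses), and the *settle* phase after
the ramp uses near-critical damping of the lowest structural mode.
That mode rides on the soft deviatoric stiffness (~4cb + 0.1σ₀ as a
scale), not on 2/D — overdamping it slows convergence to ω²/c — so the
settle coefficient is computed from the soft wave speed and the mesh
extent.  Reactions are read after the settle hold; the
kinetic/internal energy ratio is recorded so quasi-staticity can be
checked (< 1e−3 in the shipped configurations), and the energy ledger
(external work = kinetic + internal + damping dissipation) closes to
about 0.1%.

Linear tetrahedra lock volumetrically at near-incompressibility (a
plain formulation over-stiffens coarse fusiform meshes by tens of
percent).  The volumetric term is therefore evaluated on a
volume-weighted *nodal* average of the element Jacobians
(average-nodal-pressure tetrahedra — element-level mean dilatation is
the identity for constant-strain elements); the force is the exact
gradient of the averaged energy, so the energy ledger and the
finite-difference force oracle remain consistent, and for a single
element or homogeneous deformation the scheme coincides with the
standard one.  With rigid (clamped) grips, near-incompressible boundary
layers at the end caps are physical and resolution-hungry; the
refinement consistency check therefore uses axial-only grips (caps free
to contract, one pinned node per cap against rigid drift), where the
reaction force agrees across a 2× refinement to < 5% and sits within
~15% of an independent 1D force-balance oracle built from the
material-point stress–strain law.  Test problem sizes (≈ 50–1200
elements, 0.1 s ramps with 0.25 s settles) are the package's desk-scale
defaults.

## Cohesive contact

Each facet centroid of surface A is projected onto surface B once, in
the reference configuration (trimesh closest-point query).  The
separation is the change of the A→B gap vector, decomposed in A's
reference normal/tangent frame; traction is componentwise
stiffness × separation up to the damage-initiation separation, beyond
which it plateaus at the initiation value — the interface is a tether,
not a fracture model — with a flag for immediate release instead.
Compression is resisted by the same linear normal law (no separate
contact formulation).  Canonical values: 0.05 N/mm³ on all components,
30 mm initiation.

## Fiber-architecture estimation

Origin and insertion patches act as inlet and outlet of a steady
incompressible potential flow (Laplace problem, linear FEM) with
impenetrable walls: uniform normal flux ±Q on the caps, one pinned
potential node, element velocities −∇φ, normalized and sign-aligned
from origin to insertion.  A full viscous CFD solve would add boundary
layers and a velocity magnitude profile, but only the *directions* are
consumed, and for channel-like muscle volumes the potential-flow
streamlines align closely with viscous ones.  Validation: fibers on a
straight cylinder are axial to well under 1°, on a 90° bent tube within
~4° of the centerline tangent (bound asserted: 15°), and the discrete
divergence residual is ~1e−14 of the inlet flux.  The inlet flux
magnitude is irrelevant after normalization.  A Dirichlet
(uniform-potential caps) variant is available by flag.

## Parametric studies

`run_sweep` executes one homogeneous elongation per parameter value and
tabulates interpolated stresses with a hash of the exact parameter set
for provenance.  `sensitivity_table` reports normalized log–log central
differences d log(output)/d log(parameter); the metric choice is this
package's (the calibration lineage it re-enacts reported sensitivities
only qualitatively).  Exact anchors used as tests: the σ₀ sensitivity
of steady isometric stress is 1 by linearity, and parameters with no
pathway to the output (e.g. the eccentric curvature in a passive
protocol) report exactly 0.

## What the synthetic problems show — and what they do not

All geometries are generated programmatically (fusiform 50 mm × 9/17.5 mm
diameters with a sin² radius blend, cylinders, bent tubes, block pairs);
no measured data ships with the package.  The tests therefore establish
internal correctness — constitutive identities, series equilibrium,
objectivity, energy consistency, cross-solver agreement, flow oracles —
not agreement with any particular experiment.  Real muscle adds fiber
dispersion and curvature, viscoelasticity, regionally varying
activation, and fascia/skin packing, none of which are modelled; the
experimental elongation data this model family was calibrated against
exist only in graphical form, so no quantitative curve match is
asserted anywhere.

## Known limitations

* Explicit quasi-statics near incompressibility is slow by nature (the
  step count scales with the bulk/soft wave-speed contrast × mesh
  resolution); there is no implicit solver.
* Linear tetrahedra without anti-locking; refine before trusting local
  stress fields, and prefer the 95th-percentile von Mises summary over
  single-element maxima.
* The cohesive pairing is fixed in the reference configuration — large
  tangential sliding does not re-pair.
* No viscoelastic matrix, fatigue, calcium dynamics or cross-bridge
  kinetics; activation is a prescribed schedule.
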