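# myofe — 3D continuum Hill-type active skeletal-muscle modelling

`myofe` is a research toolkit for the mechanics of active skeletal
muscle for biomechanists who want a transparent, scriptable
implementation of the standard continuum treatment: muscle as a
quasi-incompressible, transversely isotropic, hyperelastic solid whose
fiber direction carries a three-element Hill rheology — a parallel
elastic element (PE) alongside a contractile element (CE) in series
with a series elastic element (SEE).

## The model

The strain energy density splits additively,

    W = W_I + W_f + W_V

with an exponential isotropic matrix part `W_I = c (exp(b(Ī₁ − 3)) − 1)`
in the isochoric first invariant Ī₁, a volumetric penalty
`W_V = (1/D)(J − 1)²` enforcing quasi-incompressibility, and a fiber
part `W_f = ∫ (σ_PE + σ_SEE) dλ̄_f` integrated over the modified
(volume-eliminated) fiber stretch λ̄_f = J^(−1/3) λ_f.  The element
stresses are

    σ_PE  = σ₀ · A (λ̄_f − 1)²          (tension only)
    σ_SEE = β (exp(α(λ_s − 1)) − 1)
    σ_CE  = σ₀ · f_λ(λ̄_f) · f_v(λ̇_m) · f_t(t)

with the classic piecewise force–length factor f_λ (peak 1 at the
optimal stretch λ_opt), the hyperbolic force–velocity factor f_v
(concentric and eccentric branches, curvatures k_c and k_e, eccentric
offset d), and an exponential activation schedule f_t between levels n₁
and n₂.  Because CE and SEE are in series they carry the same stress;
each time increment the SEE stretch increment Δλ_s solves the scalar
governing equation

    (w₂ + w₃ Δλ_s) e^(α Δλ_s) − w₄ Δλ_s − w₅ = 0

whose coefficients follow from the series kinematics
λ_m = ((1+k) λ̄_f − λ_s)/k (k = CE/SEE rest-length ratio).  The Cauchy
stress assembles the deviatorically projected matrix and fiber terms
plus the volumetric pressure (2/D)(J − 1).

Around the constitutive core the package provides:

* `myofe.uniaxial` — homogeneous uniaxial-stress driver for the
  canonical passive/active elongation protocols (5 mm/s on a 50 mm
  specimen, 0.5 s activation hold),
* `myofe.fem` — a minimal explicit total-Lagrangian tetrahedral FE
  solver (lumped mass, central difference, mass scaling, settle-hold
  quasi-statics) with 95th-percentile von Mises reporting,
* `myofe.cohesive` — linear traction–separation cohesive contact that
  tethers adjacent structures in tension while permitting sliding,
* `myofe.fiber` — flow-based fiber-architecture estimation (potential
  flow from origin to insertion, velocity directions = fiber directions),
* `myofe.fixtures` — programmatic fusiform / cylinder / tube / two-block
  test geometries, `myofe.meshio_vtk` — legacy-ASCII VTK I/O,
* `myofe.sweep` — parametric sweeps and log–log sensitivities,
* a thin CLI: `myofe elongate | mesh | fibers | fe-run | sweep`.

## Worked example

```sh
python examples/01_isometric_activation.py
```

```
held stretch 0.95: steady fiber stress    674.6 kPa (SEE stretch 1.6516)
held stretch 1.00: steady fiber stress    693.7 kPa (SEE stretch 1.6543)
held stretch 1.05: steady fiber stress    700.0 kPa (SEE stretch 1.6553)
held stretch 1.10: steady fiber stress    693.7 kPa (SEE stretch 1.6543)
held stretch 1.20: steady fiber stress    642.9 kPa (SEE stretch 1.6467)
```

Held isometric at the optimal stretch 1.05 under full activation, the
series pair equilibrates at exactly σ₀ = 700 kPa — the maximum isometric
stress — because the force–length, force–velocity and activation factors
are all 1 there; at other stretches the force–length factor scales the
plateau down.  `examples/02_elongation_curves.py` prints the passive and
active engineering stress–strain curves to 20% strain (the active curve
sits above the passive one at every strain), and the remaining examples
demonstrate fiber estimation, the FE cross-check, parameter sweeps and
the cohesive patch.

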