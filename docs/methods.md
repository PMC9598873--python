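# Methods

## Model and assumptions

The bundle is treated as a one-dimensional packed bed at steady state:
plug blood flow along the axis, no radial structure, no axial dispersion,
and all mass-transfer resistance lumped into the blood-side film (membrane
and gas-side resistances are neglected, as is appropriate for microporous
fibers with pure-O₂ sweep). The sweep gas is represented only by constant
average partial pressures (defaults 4 mmHg CO₂, 700 mmHg O₂); no gas-side
balance is solved. Blood pH is held constant along the bundle (the
venous-to-arterial pH change is ~0.5 %). Temperature and 2,3-DPG shifts of
the dissociation curves, the Bohr effect (PCO₂ feedback on the O₂ curve),
pressure drop, and hemolysis are out of scope.

The axial state is (PCO₂, PO₂). CO₂ content is carried through the power
law C = q·P^t; O₂ content is α_O₂·P + C_T·(Hb/100)·S(P) with Hill
saturation S. Substituting each content relation into its species mass
balance gives two first-order ODEs in z, integrated together with
classical fixed-step RK4.

### Haldane coupling

Whole-blood CO₂ content comes from the Visser/McHardy empirical relation
applied to Henderson–Hasselbalch bicarbonate. The hemoglobin correction is
implemented in the division form

    C = 2.226·HCO₃⁻·[1 − 0.02924·Hb / ((2.244 − 0.422·SO₂)(8.74 − pH))] / 100,

(mL/mL; SO₂ a fraction), which yields ~0.548 mL/mL at the venous default —
in the physiological band — and is strictly decreasing in SO₂, the Haldane
direction. A multiplication-form reading of the correction yields ~0.05
mL/mL, an order of magnitude below physiological, and was rejected.

The power-law exponent t is pinned by the Peters slope relation: the fitted
curve must reproduce C(60 mmHg) − C(30 mmHg) = 0.4542·Hb + 6.3 in mL/dL.
Given an anchor (P, C) — in the Haldane variant the *local* (PCO₂,
McHardy content at local SO₂) at every RK4 stage evaluation — t is found by
a bracketed root solve (`scipy.optimize.brentq`) on t ∈ (10⁻⁶, 5) with the
residual verified below 10⁻¹⁰, then q = C/P^t reproduces the anchor
exactly. The derivative function is therefore a pure function of state.
The static (no-Haldane) variant fits once, for fully saturated blood at
Hb = 15 g/dL anchored at the inlet PCO₂ (45 mmHg by default), and holds
(q, t) fixed.

### Mass-transfer coefficients

Sh = a·Re^b·Sc^⅓ with a = 0.54, b = 0.42 (measured in water for this
bundle class). Re uses the superficial velocity, a packing correction
ψ = 0.91, and the packed-bed specific surface 6(1−E)/d_p. The equivalent
particle diameter defaults to d_p = 6(1−E)/a_v — i.e. the specific surface
defaults to the tabulated area-to-volume ratio (55 cm⁻¹, implying
d_p ≈ 0.0567 cm) — because the published sphere-equivalence formula is
dimensionally unusable with a total-bundle fiber area; d_p is exposed as a
config override. For CO₂ the Sherwood diffusivity is the facilitated value
D_f = D_CO₂ + D_HCO₃·(dC/dP)/α_CO₂ and the Schmidt diffusivity the
effective value D_f/(1 + (dC/dP)/α_CO₂); for O₂ the Sherwood diffusivity
is molecular D_O₂ and the Schmidt diffusivity
D_O₂/(1 + C_T·(Hb/100)·(dS/dP)/α_O₂). Both dissociation-curve slopes are
evaluated locally, so k varies along the bundle. With the kinematic
viscosity appearing in both Re and Sc, one field ν_b = 0.023 cm²/s serves
both.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| α_CO₂ | 6.62×10⁻⁴ | mL/(mL·mmHg) | CO₂ solubility in blood |
| α_O₂ | 3×10⁻⁵ | mL/(mL·mmHg) | standard per-mL O₂ solubility; some tabulations print a per-dL-scaled figure, so this is configurable |
| D_CO₂, D_HCO₃, D_O₂ | 7.39×10⁻⁶, 4.62×10⁻⁶, 1.8×10⁻⁵ | cm²/s | diffusivities in blood |
| C_T | 1.34 | mL O₂/g Hb | used in the O₂ content relation; the Peters coefficient 0.4542 instead embeds the rounded 1.36 capacity, each kept as conventionally printed |
| Hb, pH | 12 g/dL, 7.4 | | venous oxygenator test conditions |
| P50, n | 29 mmHg, 2.85 | | adult bovine blood Hill parameters |
| inlet PCO₂, SO₂ | 45 mmHg, 0.65 | | venous inlet |
| bundle | A=16 cm², a_v=55 cm⁻¹, A_f=6700 cm², d_f=0.038 cm, E=0.48, L=7.9 cm | | ModELAS |
| n_steps | 1000 | | RK4 steps; results change <10⁻⁶ relative on step doubling |

The bundle's rated envelope is 0–600 mL/min; higher flows (up to the
1000 mL/min tested envelope) simulate normally with a warning.

## Numerical choices

* Fixed-step classical RK4; fully deterministic, no randomness anywhere in
  the pipeline. At n_steps = 1000 the outlet state agrees with an adaptive
  RK45 reference (rtol 10⁻¹⁰) to better than 10⁻¹⁰ relative.
* The CO₂ removal rate is reported two ways. `vco2_flux` — the composite
  trapezoid of the local membrane flux A·a_v·k_CO₂·(PCO₂ − P̄_CO₂,g) — is
  the primary figure: it is what the model's ODE actually removes across
  the membrane. `vco2_content` — Q_b·(C_in − C_out) by the McHardy content
  at the endpoint states (fitted-curve content in the static variant) — is
  also reported and the discrepancy logged. In the Haldane variant the two
  differ substantially (content-based ≈ 2.7× flux-based at 500 mL/min):
  the ODE's pressure drawdown follows the fitted slope t·C/P (t ≈ 0.31)
  while the McHardy content is linear in PCO₂ at fixed SO₂ (slope C/P),
  and the strong content drop from rising SO₂ is not returned through the
  membrane by the model. This is an internal inconsistency of the modelled
  chemistry, not of the integrator; flux is the number to quote.
* Degenerate inputs: zero flow returns zero film coefficients; exhausted
  gradients (PCO₂ reaching the sweep value or PO₂ the sweep value) clamp at
  the asymptote with a warning; the t-root bracket failing to change sign
  raises with both endpoint residuals.
* Exact-flow matching (no interpolation) when joining predictions to
  measurements, to avoid inventing a response surface.

## What the defaults emulate, and limits

The default configuration reproduces a standard in vitro oxygenator
characterization: bovine blood conditioned to venous targets, flows of
order 100–1000 mL/min, pure-O₂ sweep. Passing tests demonstrate internal
consistency (conservation, monotonicity, solver convergence, curve-fit
fidelity) and the qualitative Haldane prediction — the static-curve
baseline overestimates CO₂ removal by ~10–14 % at the benchmark flows.
They do not validate the model against real measurements: benchtop rates
(and their percent errors) require user-supplied data, which the package
deliberately does not bundle. The empirical chemistry is trustworthy
roughly over PCO₂ 20–80 mmHg (power-law linearity on log coordinates) and
30–60 mmHg (Peters relation); predictions degrade outside those ranges.
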