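# Methods

## Scope and model

`pbreactor` models the steady-state, isothermal operation of a small packed
bed of immobilized lipase resolving racemic 2-pentanol with vinyl butyrate
in n-hexane. One spatial dimension is retained; radial dispersion,
intraparticle diffusion limitation, pressure drop, enzyme deactivation and
transient start-up are outside the model. Both reacting species — the
(R)-enantiomer `CR` and the acyl donor `CA` — satisfy

    Dz C'' − u C' − R(CR, CA) = 0,   u = U0/ε,
    C(0) = C0,   C'(L) = 0,

with the same volumetric Ping Pong Bi Bi sink
`R = r''(CR, CA)·me/(ε·V)` (1:1 stoichiometry), so `CA − CR` is an exact
invariant of the continuous problem and its discrete defect is a solver
diagnostic. The reaction term enters as a sink: the substrate is consumed
along the bed, consistent with conversion rising as residence time grows.
The slow (S)-enantiomer is treated as strictly inert (`CS ≡ CS0`),
supported by the near-perfect enantioselectivity (eeS > 99%) observed for
this enzyme–substrate pair; eeS predictions therefore use constant CS.

The inlet condition is Dirichlet by default. The conventional Danckwerts
flux-continuity inlet (`u·C0 = u·C(0) − Dz·C'(0)`) is available behind
`inlet_bc="danckwerts"` but off by default, since the plain concentration
inlet is what the bench model used. At the operating Péclet number (≈ 50)
the two differ by ~1 mM at the outlet of the base case.

### Units

Internally geometry and transport are SI; concentrations stay in mM
(numerically identical to mol/m³). The volumetric sink follows
`r''[mmol/g/min]·me[g]·1000/(V[mL]·ε)` mM/min, divided by 60 for mM/s —
the enzyme mass enters in grams, with the factor 1000 converting mL to L
(a units audit of the rate term: 2.234 mmol g⁻¹ min⁻¹ × 0.27 g in a
0.628 mL bed of void fraction 0.3 gives 53.4 mM/s, the only reading that
produces sensible volumetric rates). All I/O uses bench units (mL/min, mM,
cm, mm, mg, min) with the unit named in each configuration key.

## Transport parameters

* Superficial velocity `U0 = 4Q/(πD²)`; interstitial velocity `u = U0/ε`.
* Residence time is the **void-volume** time `τ = εV/Q`: it reproduces the
  quoted 0.04 min at 5 mL/min and places the 0.25–1 min regimes inside the
  pump's 0.1–1.0 mL/min range, which the total-volume definition `V/Q`
  does not.
* The particle Reynolds number uses the superficial velocity,
  `Re = dp·U0·ρ/μ`. The carrier-fluid defaults are handbook values for
  n-hexane at 30 °C (ρ = 650 kg/m³, μ = 2.8×10⁻⁴ Pa·s); they close the
  audit `Re = 7.69` at the design point and are overridable in the
  configuration.
* `Dz` is evaluated from a tabulated correlation of the group
  `Dz·ε/(U0·dp)` versus `Re`, interpolated log-log with constant
  extrapolation beyond the table. The shipped table is a single anchor
  `(Re = 7.69, group = 2.0)` obtained by inverting the design-point value
  `Dz = 2.21×10⁻⁵ m²/s`; users working far from this regime should supply
  a richer table. A consequence of the single anchor: `Dz ∝ U0`, so the
  Péclet number is flow-independent (`Pe = L/(2dp) = 50`) across sweeps.

## Numerical solution

**Main solver.** `scipy.integrate.solve_bvp` (collocation with adaptive
mesh, the same algorithm family as MATLAB's `bvp4c`) on the
nondimensionalised first-order system `[CR, CR', CA, CA']` in `ζ = z/L`.
Default residual tolerance 1e-8. The initial guess is the plug-flow
profile (see below); with it the nonlinear solve converges in one or two
iterations at the operating Péclet. After convergence the solve is
repeated on a midpoint-refined mesh until the outlet CR changes by less
than 0.1% (at most three refinements; the first refinement already
changes it by ~1e-6 relative in practice). Concentrations are clamped to
zero inside the rate evaluation only, so intermediate iterates cannot
poison the rate law; a converged solution that undershoots zero by more
than `1e-9·max(CR0, 1)` mM is rejected as a solver failure, never clamped.

For `Pe > 500` (reachable only by scaling Dz far below the correlation
value) the outlet boundary layer has width and amplitude ~1/Pe, and
chasing it at tol 1e-8 exhausts any mesh budget; the tolerance is floored
at 1e-6 there and layer nodes are seeded geometrically. Cross-checks at
tol 1e-7 put the induced outlet error near 1e-10 relative.

**Plug-flow limit.** `u·dCR/dz = −R(CR, CA0 − CR0 + CR)` integrated with
DOP853 at rtol 1e-10; doubles as the `Dz → 0` oracle and as the initial
guess for the BVP (the full plug-flow profile is used rather than a
two-point linear interpolant — strictly more information at no extra
cost, since the integration is needed anyway).

**Independent oracle.** A finite-difference damped-Newton solver on a
uniform grid (default 2001 nodes/species): second-order central interior
stencils, Dirichlet inlet row, second-order one-sided outlet-gradient row,
analytic sparse Jacobian (`∂r/∂CR = Vmax·KR·CA²/D²`,
`∂r/∂CA = Vmax·KA·CR²/D²`). It shares no code path with `solve_bvp`; the
two agree to ~2×10⁻⁴ % of CR0 at the base case and to well under 0.5%
across randomized configurations.

## Performance metrics

Conversion is reported on two bases, deliberately: the racemate basis
`1 − (CS+CR)/(CS0+CR0)` (ceiling 50% for perfect resolution) and the
fast-enantiomer basis `1 − CR/CR0`. A bare "50% conversion" is ambiguous
between them, and at the 0.04 min design point the model yields 31.6% on
the racemate basis but 63.2% per-enantiomer; the package reports both
rather than asserting either as *the* conversion. For an equimolar
racemate with inert S the identity `eeS = c/(1−c)` (fractions) ties the
two metrics and is tested to 1e-12.

Model-driven productivity takes `CP = CR0 − CR(L)` (1:1
transesterification stoichiometry). Published bench productivities
(0.789/1.064/1.341 mmol min⁻¹ g⁻¹ at 3/4/5 mL/min versus 0.363 batch)
derive from measured outlet concentrations that were never tabulated
(they imply CP ≈ 71–72 mM rather than the nominal 75 mM at exactly 50%
conversion); the package's comparison table therefore labels model-derived
values as predictions, not reproductions.

## Synthetic observations

`generate_observations` emulates the chiral-GC outlet assay: for each
operating point the dispersion model provides the truth, and each species
in each replicate is reported as `truth × (1 + e)`, `e ~ N(0, σ²)`,
truncated at zero, with σ = 2% by default — the scale of peak-area
relative error in GC quantification — and duplicate measurements by
default, matching the study design. The default design grid spans
Q ∈ {0.19, 0.25, 0.38, 0.75, 3, 4, 5} mL/min (τ ≈ 1 min down to
0.04 min) × equimolar loads {100, 150, 200, 300, 500} mM, where a load of
`X` mM means `X/2` mM of each enantiomer plus `X` mM acyl donor. One
integer seed drives everything; equal seeds give byte-identical tables.

What the generator does **not** emulate: drift of enzyme activity over
operation time, autocorrelated pump pulsation, detection limits/censoring,
and calibration bias. Tests passing on these synthetic data show the
estimation machinery is self-consistent under the stated noise model, not
that real GC data would behave as benignly.

## Parameter estimation

`fit_kinetics` recovers (Vmax, KA, KR) — optionally plus a dispersion
scale — from outlet CR observations by nonlinear least squares
(Levenberg–Marquardt in log-parameter space, which enforces positivity).
Design choices that matter:

* **Residual weighting.** The default residuals are log-ratios
  `log(CR_obs/CR_model)`, the maximum-likelihood-matched choice for
  multiplicative noise (equal to relative residuals to first order) and
  linear in the effective rate constant where the outlet is nearly fully
  converted (`CR ≈ CR0·e^{−kτ}`), which keeps the optimization
  well conditioned. This matters scientifically: with unweighted absolute
  residuals the constant KA is close to unidentifiable at this reactor's
  conditions (relative standard error ≈ 60% at 2% noise), because the
  acyl donor is always in two-fold excess and the KA·CR term contributes
  little to the denominator at moderate conversion — the KA information
  sits in the deeply converted low-flow observations that absolute
  residuals effectively ignore. `weighting="absolute"` is available for
  homoscedastic data.
* **Multi-start.** Five seeded starts, log-uniform within a factor 10 of
  the initial guess; lowest cost wins. Model solves are warm-started per
  operating point from the previous iterate's profile; hopeless solves at
  extreme trial kinetics are cut off early (mesh cap) and penalised.
* **Finite-difference steps** for the Jacobian are 1e-3 in log-space —
  large enough to dominate the BVP solver's own noise floor, which
  defeats the default machine-epsilon steps.
* **Identifiability guards:** at least `max(3, n_params)` observations
  over at least two distinct operating points, else an error.
* **Uncertainty:** Gauss–Newton standard errors from the Jacobian at the
  optimum, plus a case-resampling bootstrap (`bootstrap_estimates`) whose
  spread tracks the Monte-Carlo scatter across independent noise
  realizations within a factor of ~3.

With the 24-point recovery design (Q ∈ {0.25, 0.5, 1, 3, 5, 7} mL/min ×
loads {100, 150, 300, 500} mM, 2% noise) typical recovery errors are a
few percent for all three constants. When the dispersion term is freed it
is fitted as a multiplicative factor on the correlation group — a single
shared Dz value would be physically inconsistent across flow rates, since
Dz tracks U0 through the correlation.

## Problem sizes and tolerances

Defaults: 201 initial mesh nodes for the collocation solver (adaptive
thereafter), 2001 oracle nodes, BVP tolerance 1e-8 (fitting mode 1e-6),
plug-flow rtol 1e-10, oracle residual tolerance 1e-9 relative to the
inlet convective flux. The randomized solver cross-check uses 20
configurations drawn from Q ∈ [0.5, 6] mL/min, loads ∈ [60, 500] mM,
Vmax ∈ [1, 8], KA ∈ [20, 150], KR ∈ [40, 200]; the bootstrap check uses
50 resamples against 20 Monte-Carlo realizations on a compact
four-point design.

## Known limitations

* The single-anchor dispersion correlation is exact only near the design
  point; extrapolation is deliberately flat, not predictive.
* Hexane density/viscosity defaults are a reconstruction consistent with
  the quoted Reynolds number; neither value was reported with the rig.
* Which printed Michaelis-type constant belongs to which substrate is not
  asserted: KA is defined positionally as the constant multiplying CR and
  KR as the one multiplying CA.
* The model under-predicts the quoted racemate-basis conversion at
  τ = 0.04 min (31.6% vs "50%"); with the printed parameter set the two
  statements cannot be reconciled on a single conversion basis, so both
  bases are always reported.
* Enzyme deactivation over operation time is not modelled; all solutions
  are fresh-bed steady states.
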