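# Methods

This note records the models, the numerical procedures, and the design
choices behind `spheromap`, in the spirit of a model-documentation page:
what is computed, under which assumptions, and where the package makes a
choice the problem statement leaves open.

## Growth-model hierarchy

All models describe the radius R(t) (μm) of a spherically symmetric
avascular spheroid, written where possible in generalised-logistic form
dR/dt = (λ/3) R f(R) with volumetric growth rate λ (d⁻¹) and crowding
function f.  The initial radius R(0) = R₀ = 10 μm is treated as known
(it is directly measurable, and R₀ ≪ R_max keeps the simple models
identifiable); every solver accepts an override.

* **Logistic** (k = 2): f = 1 − R/R_max.  Closed form.
* **Bounded Gompertz** (k = 2): f = min(log(R_max/R), 1), i.e. exactly
  exponential growth while R < R_max/e, then Gompertz relaxation.  Both
  regimes have closed forms joined continuously in value and slope.
* **Richards** (k = 3): f = 1 − (R/R_max)^β.  Solved in closed form via
  the substitution u = (R/R_max)^β, evaluated in log space so it stays
  accurate as β → 0⁺.  β = 1 recovers the logistic model exactly; the
  standard Gompertz model is the β → 0⁺ limit *with the rate rescaled as
  λ/β* (at fixed λ the printed form freezes growth in that limit).
* **Radial-death** (k = 3): living cells occupy a rim of thickness R_d;
  the necrotic core of volume N = (4π/3) max(0, R − R_d)³ loses mass at
  rate ζ.  The implemented radius ODE comes from the two-compartment
  volume balance dV/dt = λV₁ − ζN, giving
  f = 1 − (1 + ζ/λ)(max(0, R − R_d)/R)³.  Growth is exactly exponential
  (closed form) until R = R_d.
* **Greenspan** (k = 4, composites Q ∈ (0,1), R_d, γ = ζ/λ, λ): the
  quasi-steady nutrient profile with Heaviside thresholds yields three
  phases with algebraic inner radii.  Phase 2: R_i = √(R² − Q²R_d²).
  Phase 3: R_n solves the cubic 0 = R³ − R_d²R − 3R R_n² + 2R_n³ and R_i
  the quartic 0 = Q²R_d²R R_i + R R_i³ + 2R R_n³ − R³R_i − 2R_i R_n³.
  Both roots are bracketed — (0, R) and (R_n, R) respectively — and
  unique there, and are found by a guaranteed bracketing method (Brent)
  at 10⁻¹² relative tolerance.  The cubic's sign convention was fixed by
  re-deriving the nutrient profile from scratch (consumption confined to
  the viable shell, no flux into the core): only the `+2R_n³` form is
  consistent with the phase-2 limit, with the quartic, and with the
  model's long-time plateau of ≈ 320 μm at the reference parameters.
  The radius ODE dR/dt = (λ/3)R(1 − R_i³/R³ − γR_n³/R³) recomputes the
  inner radii at every evaluation.

ODE segments use adaptive explicit Runge–Kutta (rtol 10⁻⁸, atol 10⁻¹⁰).
The pure-exponential early phases are evaluated by their closed forms and
integration starts exactly at the phase boundary, so the min/max kinks
never sit inside an integrator step; the remaining phase switches are
continuous in value and slope and are handled by the tight tolerances.
Every closed form is cross-checked against brute-force re-integration in
the test suite.

## Ward–King multiphase model

The simplified Ward–King model evolves the living-cell fraction
n(r, t), the cellular-material fraction p = 1 − n (no voids), and a
nutrient c(r, t) in diffusive equilibrium.  Growth k_m(c) and death
k_d(c) are Hill functions with exponents m₁ = m₂ = 10 (near-switch
behaviour); nutrient is consumed at αk_m(c)n.  The no-void constraint
forces div(v) = −D_p ∇²n, hence v = −D_p ∂n/∂r, and the boundary moves
with dR/dt = v(R, t) subject to the material-flux condition
−D_p ∂n/∂r = −Q_p(1 − p₀ − n) at r = R.

Numerics (re-engineered from standard practice for moving-boundary
reaction–diffusion problems): Landau transformation ρ = r/R(t) to the
fixed domain [0, 1]; second-order central differences on a uniform ρ
grid (default n_ρ = 101); the coordinate singularity at ρ = 0 replaced
by the symmetry limit ∇² → 3∂²/∂r²; the boundary Robin condition imposed
through a ghost node.  Central (rather than upwinded) advection is used
because the material diffusivity makes the cell Péclet number of the
grid ≪ 1 throughout.  The nutrient two-point boundary value problem
(c′(0) = 0, c(1) = 1) is re-solved at every right-hand-side evaluation by
a damped, projected Newton iteration with a tridiagonal Jacobian,
warm-started from the previous solve.  Time stepping uses a stiff
adaptive integrator (LSODA, rtol 10⁻⁶).  Mesh-refinement convergence
(< 0.5% radius change when doubling n_ρ) is enforced in the tests.

Reference parameters: the printed source for this model leaves several
values undetermined (an initial-guess vector with more entries than
parameters, and blank table entries for p₀ and n₀).  The package
therefore fixes a documented reference set
p₆ = [λ, δ, c₁, c₂, α, D_p, Q_p, p₀] = [1, 1.5, 0.4, 0.3, 5·10⁻⁴,
6·10⁵, 3·10⁴, 0.1] with n₀ = 1, chosen once so that the solution
qualitatively tracks the reference Greenspan trajectory (sigmoid growth
saturating near 320 μm by day 21); α is expressed in the units of the
quasi-steady nutrient equation posed in dimensional radius (μm⁻² d).
At this point the FIM spectrum shows two eigenvalues ≈ 10 and 4 decades
below the informative cluster, the expected two-sloppy-direction
structure for radius-only data.

## Noise model and inference

Observations are y_k = R(t_k) + ε_k with ε_k ~ N(0, σ²) i.i.d. and σ
known (default scenarios: σ = 20 μm on daily observations over 0–21 d;
σ = 2 μm on 22 equally spaced times over 0–5 d for the early-time
scenario).  The log-likelihood uses the full n-observation normalisation
−n log(σ√2π) − SSE/(2σ²); profile shapes and AIC differences are
unaffected by the additive constant.  Negative simulated radii at small
R₀/large σ are kept as generated — clipping would bias the noise model.

Fitting is bounded Nelder–Mead on log-transformed parameters (so the
search respects positivity and spans orders of magnitude), tolerance
10⁻¹⁰ on the objective, with restart cycles and deterministic
tie-breaking (highest likelihood, then smallest parameter norm).
Profiles fix one parameter on a log grid (41 points on [p̂/100, 100p̂]
by default; the MLE is always inserted into the grid so the profile
attains 0) and optimise the rest, seeded from three starts — the MLE,
the previously profiled point, and the initial guess — keeping the best.
Classification against the 95% likelihood-ratio threshold −χ²₁(0.95)/2 ≈
−1.92: crossings on both sides of the maximiser → identifiable; one →
one-sided; none → non-identifiable.  Confidence bounds are linear
interpolations of the threshold crossings.

## Fisher information and sloppiness

The sensitivity Jacobian ∂R(t_k)/∂p_j uses central differences with
relative step 10⁻⁴ (optional Richardson extrapolation).  The FIM is
F = JᵀJ/σ².  The σ⁻² factor is the standard Gaussian-noise scaling;
everything the sloppiness analysis consumes — normalised spectrum,
eigenvectors, rank, gap structure — is invariant to it.  Eigenvector
signs are canonicalised (first nonzero component positive).  The
"sloppy count" splits the log-spectrum at its largest gap, provided the
gap spans ≥ 3 decades (configurable).

The sloppy path integrates dp/ds = v₁(p) with fixed-step RK4 in
coordinates scaled by the starting parameters (the arclength
parameterisation is arbitrary, so a scale-free step of 10⁻² is used),
with eigenvector sign continuity enforced and steps halved when the
direction field turns abruptly (eigenvalue crossings).

## The model map and its geometry

f_ij is evaluated by multi-start Nelder–Mead on the surrogate's
log-parameters against the noise-free source prediction on the standard
daily 0–21 d grid (the design is an argument everywhere).  R² is
computed against the source-prediction mean.  The self-map returns the
source parameters exactly with R² = 1.

Because f_ij is defined through an inner optimisation, its derivatives
are delicate.  The map Jacobian therefore (i) warm-starts every
perturbed fit from the anchor's fitted surrogate parameters, and
(ii) combines central differences at steps h and h/2 (initial relative
step 10⁻³) by Richardson extrapolation, shrinking the step until the two
levels agree to 10⁻³ entrywise relative; entries whose relative
sensitivity is below 10⁻² %-per-% are treated as zero in the agreement
check, since at that scale the comparison would be noise against noise.  The relative sensitivity
matrix is S^(k1,k2) = (p_i^(k2)/p_j^(k1)) J^(k1,k2) — the orientation
that realises the "% change in surrogate parameter per % change in
source parameter" reading; a `convention` switch provides the reciprocal
scaling.  These derivatives are validated in the tests against the
radial-death→logistic reference sensitivities, which they reproduce to
every digit reported.

Constant-feature manifolds are traced by per-gridline one-dimensional
root-finding of the feature residual (bracketing by coarse scan, then
Brent), so that every returned point is residual-certified to 0.5%
relative; gridlines without a bracketed root are omitted with a log
entry.  The tangent-plane diagnostic restricts the two Jacobian rows to
a 3-parameter slice, forms their cross product, and compares it by
|cosine| against the sloppiest eigenvector of the slice-restricted FIM.
Steering applies a multiplicative update p ← p(1 + d) with d the chosen
sensitivity row — or its component orthogonal to the remaining rows —
scaled so the linearised prediction of the targeted feature's relative
change matches the request; the linearisation is trustworthy for moves
of roughly ≤ 20%.

## Synthetic data and scenarios

The generator draws replicate r of a scenario from a deterministic
sub-seed derived from (seed, r), so datasets are bit-reproducible and
replicates independent.  Scenarios: `main` (Greenspan [0.8, 150, 1, 1],
R₀ = 10 μm, t = 0…21 d daily, σ = 20 μm), `early_time` (22 times on
[0, 5] d, σ = 2 μm), and `noise_sweep` (σ ∈ {5, 10, 20, 40} μm, 100
replicates; the σ grid is a package choice, exposed as an argument).
The generator emulates additive homoscedastic Gaussian measurement error
only; real spheroid data additionally carry biological replicate
variability, possible size-dependent error, and inner-structure
measurements, so passing tests demonstrate correctness of the machinery
under the stated noise model, not robustness to those effects.

## Problem sizes in the test suite

The stochastic panels are reproduced as scaled-down experiments chosen
as sensible defaults for a laptop-class run: AIC comparisons use 2–3
replicates instead of 100, profile grids use 9–21 points instead of
dense sweeps, manifold slices use 3×3 gridlines, and the Ward–King mesh
uses 41–101 nodes.  All qualitative conclusions (AIC
indistinguishability at realistic noise, identifiability
classifications, spectral gap structure, feature-steering behaviour) are
asserted at these sizes; the CLI workflows expose the full-size settings
through their config files.

## Known limitations

* All map-based quantities are local linearisations about the anchor
  point; the λ manifold is visibly curved at larger distances, and
  sensitivity matrices computed elsewhere on the near-constant-likelihood
  curve may differ.
* Small off-diagonal sensitivity entries (|S| ≲ 0.05) are the hardest
  quantities in the pipeline: they sit beneath an argmin evaluated by a
  derivative-free optimiser.  The package stabilises them by warm starts
  plus step-adapted Richardson extrapolation and verifies step-halving
  agreement, but quotes them to two significant figures at best.
* The Ward–King scheme is a re-engineered standard method-of-lines
  treatment; its reference parameters are a documented package choice,
  and analyses involving them are qualitative.
* σ is treated as known throughout; no estimation of the noise scale,
  non-Gaussian noise, or Bayesian posterior analysis is provided.
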