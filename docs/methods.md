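# Methods

## Model class

`structpop` works with physiologically structured population models in
which every individual is described by a single scalar state `x` (size,
volume, physiological age), develops deterministically at rate
`g(x, E)`, dies at rate `mu(x, E)` and reproduces according to a birth
kernel `beta(x, E, ·)` — a rate measure over states-at-birth.  The scalar
environmental condition `E` (in the chemostat models the substrate
concentration `S`) is either a prescribed function of time or evolves by
a feedback ODE coupled to population outputs.  Vector-valued
environments and multi-dimensional individual states are out of scope;
`E` is scalar throughout, with the vector case left as an extension
point.

Rather than discretizing the transport PDE for the population density,
the package works with the renewal equation for the population birth
rate: transporting an individual born at time `s` in state `xi` along
the flow `X_E(t, s, xi)` of `g` and discounting by the survival
probability `exp(-∫ mu)` gives the rate at which that individual
produces offspring at time `t` (the generation kernel).  The birth rate
`b(t)` is the fixed point of the corresponding Volterra integral
equation, and the population measure `m(t)` is an explicit pushforward
of past births.  Four kernel forms are built in: point birth (single
state at birth `x_b`), fission into equal halves with success
probability `p` (a failed attempt removes the mother), the *net* fission
kernel `beta0 (2 δ_{x/2} − δ_x)` in which mother removal is part of the
kernel, and finite separable sums `Σ_j beta_j(E, ·) w_j(x)`.  For
simulation the net kernel's negative part is folded into an effective
death rate, so every transported mass stays non-negative.

## Numerical scheme

**Measures as cohorts.**  All measures (birth rates per time step and
the population state) are weighted atom lists.  This follows the
pushforward structure of the model exactly and introduces no numerical
diffusion: fission deposits offspring as new cohorts at `x/2`, with no
grid interpolation.  Optional cohort merging coalesces atoms into bins
of configurable width (in `log x` for positive state intervals),
conserving total number and the first moment exactly.  Merging is off
by default in the low-level API; the simulation drivers enable it
(default bin width `2e-3` in `log x`) because unmerged fission cascades
grow combinatorially.  The merge bias is quadratic in the bin width and
is invisible at the default setting (verified by varying the width over
an order of magnitude).

**Time stepping.**  Uniform step `dt`.  Cohort positions advance with
classical RK4; survival uses the trapezoid rule on the step endpoints.
Births within a step are integrated by the trapezoid rule (mother
weights at both endpoints), injected at the mother's midpoint position,
and transported over the remaining half step.  A second-generation
correction adds the births of within-step newborns
(`0.5 dt^2 × rates²`); without it the stepper is only first-order
accurate in the reproduction terms, with it the scheme is second order
(verified empirically by `dt` halving).

**Generation expansion.**  `solve_renewal` constructs `b = Σ_n b_n`
with `b_0` the forcing produced by the initial history and `b_{n+1}`
the offspring rate of generation `n`, each generation computed by one
sweep that transports all source atoms across the grid (trapezoid
quadrature in the birth-time variable).  All terms are non-negative, so
partial sums increase monotonically; iteration stops when a
generation's integrated mass falls below `tol_gen` (default `1e-8`)
times the accumulated total, and a geometric-ratio truncation estimate
is attached.  Exceeding `max_generations` raises an explicit error with
the per-generation masses.  The direct time-stepping driver
(`simulate_structured`) solves the same equations by spawning births
step by step; the two routes agree to discretization error and are
cross-checked in the test suite.

**Histories.**  Initial data are finite atom lists on `(-∞, s]`
("point cohorts" at `t = s`, or earlier atoms transported to `s` by
flow and survival).  Densities (uniform bands, truncated Gaussians) are
discretized by the fixtures module into midpoint atoms normalized
exactly to the stated total mass.  Unbounded-support histories must be
truncated by the caller; only finite representations are supported.

**Domain truncation.**  The state interval is finite.  Offspring that
would fall below `x_min` are deposited at `x_min`; cohorts leaving
through either end are clipped.  Both events are counted and reported
(`truncated_mass`), never silent.  Fission models need generous domains
because the number- and biomass-weighted size distributions drift and
diffuse at different rates (see *Study conditions* below).

**Chemostat coupling.**  `simulate_coupled` splits each step: the
substrate is advanced half a step by its current rate, the population
is stepped with the substrate frozen at that midpoint value, and the
substrate completes the step using the trapezoid average of the uptake
functional `gamma · u(S) · ∫ w_u dm`.  A step that would drive `S`
negative is rejected and retried with halved substeps (at most 8
halvings, then clamped at zero).  Consistency under `dt` halving is
asserted in the tests.

**Flow/survival primitives.**  The single-trajectory operations use
`scipy.integrate.solve_ivp` (RK45, `rtol 1e-8`, `atol 1e-10`, both
configurable); survival exponents use the trapezoid rule on the
trajectory grid.

## Reducibility analysis

A weight family `w : Omega → R^k` closes into `dN/dt = K(E) N` exactly
when `g w' − mu w + ⟨w, beta⟩ = K(E) w` identically in `x`.  All
verdicts are numeric on grids:

* `fit_K` solves, per sampled `E`, the least-squares problem for the
  `k²` entries of `K(E)` and compares the relative residual
  `‖R‖/‖LHS‖` with the tolerance — default `1e-8` for analytically
  specified rates, `1e-5` recommended for tabulated ones.  Where a
  closed-form `K` exists the consistent least-squares system reproduces
  it to rounding.
* `k1_test` implements the scalar criterion: the expression
  `(g w' + ⟨w, beta⟩)/w − mu` must be independent of `x`; the verdict
  compares its range (max − min) against `tol × max(1, |K|)`.
* `extend_weights` implements the systematic search for additional
  output components: evaluate the condition LHS, project out the span
  of the current components (coefficients may depend on `E`; per-`E`
  least squares), test whether the remainder factorizes as
  (function of `E`) × (function of `x`) by the singular-value ratio
  `σ2/σ1 < 1e-6`, and append the extracted profiles (sup-norm
  normalized, orthogonalized against the current family in the grid
  inner product, represented as cubic splines with analytic spline
  derivatives).  Success means the family closes under the condition;
  failure is reported when `k` exceeds `k_max` or a remainder is not
  separable.  Two numerical choices matter here.  First, for halving
  kernels the pairing evaluates components at `x/2`, so all decisions
  are restricted to `x ≥ 2 min(grid)`, where interpolated components
  are evaluated strictly inside their support.  Second, the remainder
  is only defined modulo the current span, so the appended basis is not
  canonical: starting from volume `w = x` on the volume/surface model
  the procedure closes at `k = 2` with a component that equals the
  surface area `x^(2/3)` *modulo* `x`, and the fitted `K` is similar
  (equal trace, determinant and spectrum) to the one obtained in the
  canonical `(x, x^(2/3))` basis.
* `solve_g_mu_from_weights` inverts the two `k = 2` condition rows for
  `(g, mu)` given two weights, their kernel pairings and the entries of
  `K(E)`, requiring a non-vanishing Wronskian on the grid.  The result
  is round-trip checked against both condition rows.  Negative values
  of the constructed `g` or `mu` are *reported* (fractions of the grid),
  never clipped: positivity is a modelling constraint to check after
  construction, not a property of the algebra.

## The catalogue families

For transport-degradation models (no reproduction, or reproduction
whose weighted offspring output is a scalar multiple `beta0(x,E) w(x)`
of the parent's — the "conserved in reproduction" case, tested by
`conserved_reproduction_check`; then `mu − beta0` takes the place of
`mu`), two families solve the reduction identity
`g w' − mu w = H(E) w` exactly:

* **F2 (physiological age)** — `g = v0(x) v1(E)`,
  `mu = gamma0 g + mu0(E)`, weights
  `w(x) = exp(∫ gamma0) · expm(zeta(x) Λ) · w(x_b)` with
  `zeta(x) = ∫_{x_b}^x dy/v0(y)`, and `H = v1 Λ − mu0 I`.
* **F3 (generalised von Bertalanffy)** —
  `g = v0 (v1 + v2 zeta + v3 zeta²)`,
  `mu = gamma0 g + mu0 + (k−1) v3 zeta`, weights
  `w_j = exp(∫ gamma0) zeta^{j−1}`, and `H = H0 − mu0 I` with `H0`
  the tridiagonal pattern ((j−1)v1 subdiagonal, (j−1)v2 diagonal,
  −(k−j)v3 superdiagonal).

The builders return callables for `g, mu, w, w', H` and verify the
identity on a grid at construction (threshold `1e-10`, scaled by the
sup of `|w|`).  The derivative `w'` is computed *analytically* via the
chain rule (`zeta' = 1/v0`), which makes the verification residual
independent of the accuracy of the `zeta` quadrature — the identity
holds for any antiderivative — so the residual measures only rounding
(matrix exponentials by scaling-and-squaring per grid point;
antiderivatives by composite 12-point Gauss–Legendre, cached as cubic
splines on an 800-point table).  A deliberately mis-specified `mu`
(e.g. `+0.1`) produces a residual of that size, confirming the check
has teeth.  Positivity of the constructed rates is reported, not
enforced.

The trigonometric growth rate
`v1(E)(1+cos x) + v2(E) sin x + v3(E)(1−cos x)` is registered as a
worked transformation: with `v0 = 1 + cos x` and `x_b = 0` the rescaled
state is `zeta = tan(x/2)` (closed form registered next to the
quadrature path as a cross-check), and the half-angle identities
`(1+cos x) tan(x/2) = sin x`, `(1+cos x) tan²(x/2) = 1−cos x` collapse
the F3 growth rate to the expression above; the default domain is
`[−π + 0.1, π − 0.1]`, keeping clear of the `zeta` singularity (the
margin is configurable).

## Asymptotic (dominant-eigenvalue) reduction

When growth, death beyond washout, and reproduction share one
environmental factor `theta(E)` — strict physiological age — the time
change `dτ/dt = theta(E(t))` makes development autonomous, and the
output built from the dominant eigenfunction `w_d` of
`g0 w' − mu0 w + ⟨w, beta0⟩ = λ_d w` obeys
`dN/dt = (−D + λ_d theta(E)) N` exactly.  The generator is discretized
on a log-spaced size grid (default 400 points) with a first-order
upwind transport stencil, chosen because it keeps all off-diagonal
entries non-negative — a Metzler matrix — so the Perron structure of
the continuum operator survives discretization.  The dominant eigenpair
comes from a dense eigensolve (grids ≤ 1000; a power iteration would be
the natural fallback for larger grids).  The Perron property is
*checked*, not assumed: a complex dominant pair or eigenvector entries
below `−1e-8` (relative) raise; smaller negative entries are zeroed
with a note.  `eigen_with_refinement` recomputes at double resolution
and attaches the relative change and the first-order Richardson
extrapolation.

For mass-conserving fission (`mu0 = beta0-hat`, `g0 = x`) the exact
eigenpair is `w = x`, `λ_d = 1`; on the truncated grid the eigenvalue
is reproduced to rounding (linear interpolation and one-sided
differences are exact on linear functions) while the eigenvector
acquires a boundary layer at small `x` where the halving map leaves the
grid — localized far below the occupied bulk and harmless for
density-weighted outputs.  In the coupled comparison the structured
population consumes substrate through the eigen-output
`N = ∫ w_d dm`, with `w_d` scaled by least squares onto the biomass
weight `x` (its exact continuum limit here), and the reduced
two-dimensional `(N, S)` system is integrated from the matched initial
output.  The report separates the transient discrepancy from the
late-time one ("late" = final 20 % of the horizon, horizon default
`10/D`) and tracks the per-capita growth rate of `N` against
`−D + λ_d theta(S(t))`.

## Study conditions (defaults of the worked systems)

All data are synthetic; the models and parameters are desk-scale study
conditions, not fits to measurements.

* **Chemostat** — `D = 0.5`, `S_ext = 2`, `gamma = 1`, `a = 1`, `b = 1`
  (all rates per unit time, concentrations in substrate units): a
  surviving culture with equilibrium `S* = 1`, `X* = 1`, comfortably
  away from washout (`monod(S_ext) = 2/3 > D`).  Runs start from a
  single cohort of size 1 and biomass 0.2 at `S(0) = 1` and last
  `10/D`.
* **Monod fission model** — constant attempt rate `beta0 = 0.5` with
  every division successful.  The fission rate does not enter the
  biomass reduction at all (it may be chosen arbitrarily), but it sets
  the size distribution's drift: `beta0 ≈ monod(S*)/ln 2` keeps the
  biomass-weighted log-size nearly stationary, so the default domain
  `[x0/2^15, 2^15 x0]` contains the distribution with negligible
  truncation.  Default `dt = 0.005`.
* **Failed divisions** (`p = 0.5`, compensated growth per the
  compensation law) — `D = 1`, `a = 2` (equilibrium `S* = 1`),
  `beta0(x) = 0.85 + 0.3 x/(1+x)`; the size dependence is what makes
  the *uncompensated* variant detectably non-reducible in the scalar
  test.  Because half of all divided biomass is destroyed and regrown
  in place, the biomass-weighted size distribution drifts upward at
  rate `≈ monod + 0.15 beta0` — an intrinsic feature of this model, not
  an artifact — so the domain spans `2^26` on each side of `x0` to
  contain the transient over the `10/D` horizon; `dt = 0.0025`.
* **Volume/surface model** — `k21 = 1` (constant, the natural first
  guess for the size-specific division factor), Michaelis–Menten
  `k12(S)`, prescribed substrate `S(t) = 1 + 0.5 sin(0.8 t)`, span
  `2^12`, `dt = 0.002`.  Growth proportional to surface area is
  self-limiting, so this model's size distribution is tightly confined.
* **Physiological age** — `theta(S) = a S/(b+S)`, `g0 = x`,
  `mu0 = beta0-hat = 0.9`, mass-conserving fission; grid 400 (refined
  to 800), span `2^17`, `dt = 0.005`.
* **Catalogue battery** — 50 seeded random draws per family per
  `k ∈ {2, 3, 4}` on `x ∈ [0.1, 2]`: `gamma0` a random affine/quadratic
  polynomial in `[−0.5, 0.5]`, `v0` a positive quadratic bounded away
  from zero, `Λ` entries uniform in `[−0.6, 0.6]`, environmental
  coefficients affine in `E`; magnitudes chosen so `zeta Λ` stays
  moderate and the matrix exponentials are well-conditioned.
  Verification grid: 200 points.

These conditions emulate continuous cultivation of unicellular
organisms limited by one substrate.  They do not emulate measurement
noise, demographic stochasticity, multi-substrate kinetics, or jumps in
the individual state — so passing tests demonstrate the correctness of
the deterministic reduction machinery, not robustness to biological or
observational variability.

## Numerical choices and degenerate inputs

* Verdict tolerances: `1e-8` (analytic rates), `1e-5` (tabulated);
  extension tolerance `1e-6` (spline-represented components cap the
  attainable residual near `1e-7`); rank-one test `σ2/σ1 < 1e-6`;
  catalogue verification `1e-10`; weight-independence check by
  normalized SVD with ratio `1e-10`.
* Weight derivatives are analytic wherever available (symbolic for
  configuration expressions); the central-difference fallback uses step
  `1e-6 · max(1, |x|)`.
* Degenerate inputs raise typed errors: negative death rates, weights
  vanishing on the grid, dependent weight components (named), vanishing
  Wronskians, non-increasing time grids, non-positive `theta` along a
  trajectory, histories with atoms after the start time.
* Determinism: the solvers contain no randomness; identical
  configuration (and seed, for randomized fixtures) reproduces output
  files byte for byte.

## Known limitations

* One-dimensional individual states only; the multi-dimensional
  condition is documented but not implemented.
* Reducibility verdicts are numeric lower bounds on grids — "not
  reducible" means no `K` fits at the stated tolerance on the sampled
  grid, not a formal proof; and the extension procedure's termination
  test (rank-one separability) is one concretization of an informally
  specified step.
* The completeness of the F2/F3 catalogue is used as background; only
  sufficiency (the identity holds for every constructed member) is
  verified, and the normal-form transformation bringing an arbitrary
  reducible model into family form is not automated (the trigonometric
  example is registered by hand).
* Point-birth (single state-at-birth) kernels are fully supported in
  simulation, but no reducibility classification is claimed for them.
* Finite domains: fission models with weak size control (notably the
  failed-division model with compensation) develop heavy or drifting
  size distributions and need — and get — very wide domains; the
  truncated mass is always reported and should be inspected.
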