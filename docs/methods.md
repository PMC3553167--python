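# Methods

## Model

An organism allocates one limited resource pool to adult survival first,
then to reproduction. Environmental selection pressure `x ≥ 0`
(dimensionless; "strength" has no natural units here) diverts resource
toward survival, so the reproductive share `E(x)` decreases strictly
monotonically toward zero. Of the reproductive share, a fraction `μ`
funds the male function and `1 − μ` the female function; female output is
linear in its resource input. With adult survival `P` and offspring
survival `C(E)`, the expected per-step growth factor of a lineage is

    λ(x, μ) = P + M (1 − μ) E(x) C(E(x)).

Assumptions worth making explicit:

- **Adult survival is constant in pressure.** Because survival is funded
  first, the survival allocation absorbs the pressure and `P` carries no
  `x` dependence; the entire effect of the environment enters through
  `E(x)`.
- **No density dependence and no demographic stochasticity.** Population
  counts are real-valued expectations; projection is exactly geometric,
  `N(t) = N0 λ^t`.
- **C depends on the total reproductive share**, not on per-offspring
  investment. A per-offspring formulation (share divided by offspring
  number) would be a different model; it is not implemented.
- **No frequency dependence.** λ contains no resident-strategy term, so
  the "evolutionarily stable" strategy here is operationally the
  strategy along which λ is stationary. A Shaw–Mohler-type
  frequency-dependent fitness would need a resident/mutant structure
  that this model deliberately omits; pointwise maximisation of λ over
  μ would degenerate (λ is strictly decreasing in μ, so the pointwise
  optimum is always μ = 0), which is why stationarity in `x` is the
  defining condition.

## The optimality ODE and its closed form

Setting dλ/dx = 0 along a strategy μ(x) and solving for the slope gives

    dμ/dx = (1 − μ) (E′/E) (1 + δ),    δ(E) = E C′(E)/C(E).

δ is the **resource elasticity of offspring survival**, kept *signed*
(the economics convention of quoting absolute elasticities is noted but
not used: the regime threshold lives at −1 on a signed axis). Since
`E′ < 0` and `1 − μ > 0` in the interior, `sign(dμ/dx) = −sign(1 + δ)`:
elasticities below −1 are the r-type regime (pressure raises male
allocation), above −1 the K-type regime, and δ = −1 leaves the sex ratio
untouched. `classify_regime` compares the supplied δ to −1 exactly, with
no epsilon: δ is a model input there, not an estimate; estimated
elasticities are classified through their confidence interval instead
(see below).

For the power family `C = c0 E^δ` the elasticity is constant and the ODE
integrates in closed form: `(1 − μ) E^(1+δ)` is conserved, so

    μ(x) = 1 − (1 − μ0) (E(x0)/E(x))^(1+δ),

and λ is *exactly* constant along the solution — the conservation law
doubles as an independent oracle for the numerical integrator.

## Curve families and their parameters

| object | family | form | parameters (defaults) |
|---|---|---|---|
| allocation | exponential | `E0 e^(−kx)` | `E0 = 0.8` share at zero pressure, `k = 0.5` decay per unit pressure |
| | rational | `E0/(1+kx)` | same |
| | linear_clamped | `E0(1−kx)` on `[0, 1/k)` | same |
| survival | power | `c0 E^δ` | `c0 = 0.5`, δ free (constant elasticity) |
| | saturating | `1 − e^(−aE)` | `a > 0`; elasticity in (0, 1) |
| | constant | `c0` | elasticity 0 |

The defaults (exponential E0 = 0.8, k = 0.5; power c0 = 0.5) make the
constant-elasticity regimes exactly realizable, so every qualitative
case of the theory can be produced by varying a single parameter.

A model is *valid* on a pressure interval when `P ∈ [0, 1)`, `M > 0`,
`E` is positive and strictly decreasing, and `C(E(x))` stays in (0, 1]
over the induced share range. `validate_model` reports violations as
diagnostics rather than raising, so a command-line run with e.g.
`P = 1.2` can fail with a message naming the violated invariant.

Because the survival *scale* `c0` cancels out of dμ/dx entirely, a scale
that pushes `C` above 1 somewhere on a sweep range says nothing about
the μ dynamics. The sweep and trajectory front-ends therefore rescale
`c0` per elasticity (capping max C at 0.5 over the traversed share
range) instead of discarding those elasticities; `rescale_c0=False`
restores strict skip-with-warning behaviour. All λ values reported under
a rescaled scale are still exact for the rescaled model.

## Numerics

- **Integrator:** fixed-step classical Runge–Kutta (RK4), default step
  1e−3, chosen over adaptive schemes so identical configurations give
  bit-identical trajectories. The final partial step lands exactly on
  the span end.
- **Boundary events:** integration stops when μ crosses 0 or 1; the
  crossing is located by bisection on the step length to ≤ 1e−9 in `x`
  and the trajectory is truncated there (no clamping), so closed-form
  comparisons stay exact. For the linear_clamped allocation the run is
  truncated just inside the domain end `1/k` with an explicit
  `domain_end` exit.
- **Finite-difference elasticity:** central difference with relative
  step `1e−6 · max(E, 1)`; the analytic path is used for all built-in
  families and agrees with the finite-difference path to ≤ 1e−6.
- **Threshold location:** `critical_elasticity` bisects the sign of
  dμ/dx in δ to absolute tolerance 1e−9 (scipy bisect); the root is the
  zero of the `(1 + δ)` factor, hence −1 for every valid
  parameterization.
- **Degenerate inputs:** μ0 must be interior; μ exactly on a boundary
  has slope 0 (the clamped system); non-increasing grids, nonpositive
  steps and out-of-domain pressures raise domain errors.
- **Output format:** tables are CSV/TSV with `%.17g` floats and the
  parsed configuration echoed as canonical JSON in a comment header;
  reading uses round-trip float parsing, so write→read is bit-exact.

## Elasticity estimation

For power-family survival, δ is exactly the slope of log C against
log E, so the estimator is ordinary least squares of the log survival
proportion on the log allocation share (statsmodels OLS). Weighted or
GLM variants are out of scope by design: the estimator operationalises
the definition of elasticity, nothing more. Groups with zero survivors
have no log proportion; they are dropped and counted in the
diagnostics (no continuity correction — a simpler, honest contract).
Confidence intervals are percentile bootstrap over `n_boot = 1000` case
resamples of the groups, which respects the heteroscedasticity of log
proportions. An estimate is classified `boundary_constant` whenever its
95% interval contains −1 — the data cannot then distinguish the
regimes — and by the point estimate otherwise.

### Synthetic data

`simulate_survival_dataset` draws independent binomial survivor counts
with success probability `c0 E^δ` per allocation level (default grid: 20
geometric points on [0.05, 0.8]), seeded through numpy's Generator so
identical seeds give identical datasets. This emulates grouped
survival assays with known allocation levels; it does *not* emulate
overdispersion, shared brood effects, measurement error in E, or
non-constant elasticity, so recovery results certify the estimator
under its own sampling model, not robustness on real field data.

### Recovery experiment

`recovery_experiment` reports bias, RMSE and 95%-interval coverage per
true δ. Its study conditions are 500 replicates of 200 groups × 1000
trials. The experiment's allocation levels span [0.2, 0.8] with the
survival scale set per elasticity so success probabilities reach 0.8:
a 4-fold range of E keeps every probability above ≈0.05 even at
δ = −2, where a wider range would push groups into the regime where
the log of a binomial proportion is badly biased and zero counts are
common — a range a practitioner would choose for an assay intended to
measure an elasticity of that magnitude. At these conditions the
measured |bias| is ≤ 0.02 and coverage sits inside [0.91, 0.98] for
δ ∈ {−2, −1, −0.5, 0.5, 1} (computed by the test suite, not quoted
from anywhere).

## Experiments

`elasticity_sweep` integrates μ from μ0 = 0.5 at x = 0 to a reference
pressure for each δ on a grid (default linspace(−3, 2, 101)) and records
both μ(x_ref) and dμ/dx there — both are emitted because either could
serve as the response variable of interest; the slope signs partition
the δ axis exactly at −1. `pressure_response_curves` emits tidy
(δ, x, μ) trajectories on a shared grid (default x ∈ [0, 3], step 0.01).
Both are deterministic: identical configurations produce byte-identical
files. PNG plots are produced only if matplotlib imports; otherwise the
tables stand alone.

## Problem sizes

The test suite and the acceptance script use spans of 1–2 pressure
units at step 1e−3 (1–2 thousand RK4 steps per trajectory), 100 random
configurations for the oracle-equivalence and threshold-invariance
checks, and the full 5 × 500-replicate recovery experiment; the whole
suite runs in well under a minute on one core.

## Known limitations

- The ESS label is nominal: without frequency dependence the model
  cannot express invasion analysis, only stationarity of λ.
- The second-order condition cannot be checked strictly along a
  dλ/dx ≡ 0 trajectory; the stationarity residual is the implemented
  sufficiency diagnostic.
- Real-data fitting (species case studies, condition-dependent
  Trivers–Willard-type allocation, density dependence) is explicitly
  out of scope.
- The closed form exists only for constant elasticity; other survival
  families rely on the RK4 path.
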