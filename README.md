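# sexalloc

Comparative statics of sex allocation when resources are limited and
survival is funded first.

## The problem

Many organisms face a three-way trade-off among adult survival, male
reproduction and female reproduction, all drawn from one resource pool.
If environmental selection pressure `x` (competition, predation, food
scarcity) forces an organism to fund survival first, the share of
resource left for reproduction, `E(x)`, shrinks monotonically as
pressure grows. How should the split `μ` between male and female
function respond?

`sexalloc` implements an evolutionarily-stable-strategy answer. With
adult survival `P`, maximum female fecundity `M`, and offspring survival
probability `C(E)`, fitness is the per-step population growth factor

    λ(x, μ) = P + M · (1 − μ) · E(x) · C(E(x)).

Along an optimal strategy λ is stationary in `x`, which yields the
governing ODE for the male share

    dμ/dx = (1 − μ) · (E′(x)/E(x)) · (1 + δ),   δ = E · C′(E) / C(E),

where `δ` is the **resource elasticity of offspring survival** — the
percent change in offspring survival per one-percent change in
reproductive allocation. Since `E′ < 0` and `1 − μ > 0`, the sign of the
response is `−sign(1 + δ)`:

| elasticity | regime | response of male share to pressure |
|---|---|---|
| δ < −1 | `r_increasing` (r-type strategy) | rises |
| δ = −1 | `boundary_constant` | constant |
| δ > −1 | `K_decreasing` (K-type strategy) | falls |

For constant elasticity (power-law survival `C = c0·E^δ`) the ODE has
the closed form `μ(x) = 1 − (1 − μ0)·(E(0)/E(x))^(1+δ)`; equivalently
`(1 − μ)·E^(1+δ)` is conserved, so λ is exactly constant along the
solution. The package also ships a seeded synthetic-data generator and
a log-log OLS estimator (with case-resampling bootstrap intervals) for
recovering `δ` from grouped binomial survival data.

## Worked example

```python
import numpy as np
from sexalloc import (
    AllocationCurve, LifeHistoryModel, OffspringSurvivalCurve,
    classify_regime, critical_elasticity, integrate_trajectory,
    simulate_survival_dataset, estimate_elasticity, stationarity_residual,
)

model = LifeHistoryModel(
    P=0.5, M=10.0,
    allocation=AllocationCurve(family="exponential", E0=0.8, k=0.5),
    survival=OffspringSurvivalCurve(family="power", c0=0.1, delta=-2.0),
)
traj = integrate_trajectory(model, mu0=0.5, x_span=(0.0, 1.0), step=1e-3)
print(f"mu(0) = {traj.mus[0]:.4f} -> mu(1) = {traj.mus[-1]:.4f} ({traj.exit_reason})")
print(f"fitness drift along the trajectory: {stationarity_residual(model, traj):.2e}")
label = classify_regime(-2.0)
print(f"regime at delta = -2: {label.regime} ({label.sub})")

root = critical_elasticity(
    lambda d: LifeHistoryModel(
        survival=OffspringSurvivalCurve(family="power", c0=0.5, delta=d)),
    x_eval=1.0, mu_eval=0.5, delta_interval=(-3.0, 0.0),
)
print(f"critical elasticity: {root:.9f}")

data = simulate_survival_dataset(c0=0.5, delta=1.0, trials=1000, seed=42)
est = estimate_elasticity(data, n_boot=1000, seed=43)
print(f"delta_hat = {est.delta_hat:.3f}, 95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}], "
      f"regime: {est.regime.regime}")
```

Output:

```
mu(0) = 0.5000 -> mu(1) = 0.6967 (completed)
fitness drift along the trajectory: 2.96e-15
regime at delta = -2: r_increasing (elastic)
critical elasticity: -1.000000000
delta_hat = 0.990, 95% CI [0.937, 1.044], regime: K_decreasing
```

At δ = −2 (elastic, r-type) pressure pushes the male share up from 0.50
to 0.70 over one pressure unit, while fitness stays constant to
floating-point accuracy — the defining property of the optimal
trajectory. The threshold separating the regimes is located at −1
independent of every other parameter, and the estimator recovers the
simulated elasticity δ = 1 inside a calibrated 95% interval.

The same operations are available from a shell:

```sh
sexalloc trajectory --delta -2 --mu0 0.5 --x-max 1 --out traj.csv
sexalloc classify --delta -2           # r_increasing (elastic)
sexalloc sweep --x-ref 1 --out sweep.csv
sexalloc recover --deltas -2,-0.5,1 --reps 100 --seed 1 --out recovery.csv
```

Every output file carries the generating configuration as a JSON comment
header, and identical configurations give byte-identical files.

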