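# invasim

Raster-based planning toolkit for managing an invasive plant on a
categorical landscape: estimate habitat suitability from a presence map
and a land-use map, validate it with the continuous Boyce index, simulate
spread with a reaction–diffusion model, compute the budget-constrained
optimal control effort in space and time, and propagate suitability
uncertainty with arbitrary polynomial chaos on a sparse grid.

It is written for quantitative ecologists and park managers who have a
binary presence raster (e.g. from satellite-image classification), a
land-use/land-cover raster on the same grid, and a limited eradication
budget, and who want to know *where and when* to allocate removal teams.

## The model

The invader's density `u(x, t)` evolves as

```
∂u/∂t = D Δu + r u (ρ(x) − u/k) − μ u E(x, t) / (1 + τ μ u)
```

with diffusivity `D` (m²/yr), intrinsic growth rate `r` (1/yr), carrying
capacity `k`, habitat suitability `ρ(x) ∈ [0, 1]` modulating the logistic
equilibrium, and a Holling type-II removal term: a control effort
`E(x, t) ≥ 0` removes `μ u E` plants per year at low density and
saturates at `E/τ` when the handling time `τ` per item dominates.
Boundaries are zero-flux (no population crosses the domain edge).

The suitability `ρ` is estimated per land-use class as the relative
frequency of that class in the neighbourhood of presence cells (edges of
woods/groves split out as extra classes, spatial k-fold for mean ± sd),
and validated with the continuous Boyce index: the Spearman correlation
between the predicted-to-expected presence ratio `F_i = P_i/E_i` in a
moving suitability window and the window's rank.

The planner minimizes the discounted, budget-penalized objective

```
J(E) = α ∫ e^{−δt} ∫ E² + β ∫ e^{−δt} ∫ E³/B³ + γ ∫ e^{−δt} ∫ u + θ e^{−δT} ∫ u(T)
```

by a damped forward–backward sweep (forward state solve, backward
costate/shadow-price solve, pointwise optimality update). Uncertainty in
the per-class suitability scores is propagated with arbitrary polynomial
chaos: moment-built orthonormal bases, total-degree-2 expansion, and a
level-1 Smolyak collocation grid needing only `2 n + 1` model runs for
`n` uncertain classes (9 runs for 4 classes).

## Worked example

```python
from invasim import (ScenarioSpec, make_scenario, kfold_scores, project_scores,
                     continuous_boyce, initial_density, simulate, total_population,
                     ModelParams, ObjectiveParams, forward_backward_sweep)

spec = ScenarioSpec(shape=(20, 20), n_classes=4, blob_scale=2.0,
                    presence_rate=0.2, seed=42)
lu, presence = make_scenario(spec)             # synthetic landscape + occurrences
hsi = project_scores(lu, kfold_scores(lu, presence, k=2))
state0 = initial_density(presence, hsi)        # u0 = presence x suitability

params, weights = ModelParams(D=50.0), ObjectiveParams(T=5.0)
policy = forward_backward_sweep(state0.u, hsi, params, weights, dt=0.05, max_iter=40)
uncontrolled = simulate(state0, None, 0.0, 5.0, 0.05, hsi, params)
print(policy.J_history[0], policy.J_history[-1])
print(total_population(uncontrolled[-1]), total_population(policy.u[-1]))
```

prints (five-year horizon, 20×20 cells of 20 m):

```
371384.79280161794 148285.37411778886
8835.511574297348 1437.6403082050317
```

The first line is the objective with no control versus the optimized
program — the sweep cuts the total discounted cost to ~40 %. The second
line is the final population integral (density × m²): the optimal effort
schedule removes ~84 % of the population the do-nothing run would leave.
The scripts in `examples/` walk through each stage the same way
(landscape generation, suitability estimation, Boyce validation, spread,
control, uncertainty) and print what the numbers mean; the `invasim`
command exposes the same stages from the shell (`invasim synth`, `hsi`,
`boyce`, `simulate`, `optimize`, `uq`, `run`).

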