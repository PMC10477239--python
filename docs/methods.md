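# Methods

This note records the models, numerical schemes, parameter defaults and
design decisions behind `invasim`, and what the synthetic test scenarios
do and do not establish about real data.

## Raster model

All layers are single-band rasters of square cells (row 0 = north, cell
edge `cellsize` metres); the interchange format is the ESRI ASCII grid,
chosen because it is pure text and needs no binary dependency (GeoTIFF is
a soft optional). Floats are serialized with 17 significant digits so
write/read round trips are lossless and reruns are bit-identical. A
`nodata` sentinel is excluded from every statistic and propagates through
layer-combining operations. Resolution degradation aggregates
`factor × factor` blocks — majority (ties to the lowest code) for
categorical layers, mean for continuous, "any presence" for binary —
which is the aggregation a workflow needs when moving from a 2 m
classification raster to a coarser simulation grid.

## Habitat suitability estimation

The suitability of a land-use class is taken proportional to how often
the class occurs near occurrences of the plant. For every presence cell,
all non-nodata cells of the square Chebyshev window of radius 1 (3×3,
centre included; truncated at borders) are tallied by class; counts are
summed over presence cells and normalized across classes, so scores are
relative frequencies that sum to 1 and a projected map is a valid
`ρ(x) ∈ [0, 1]`. Design choices where the procedure is genuinely open:

* **Window radius** defaults to 1 cell and is configurable; larger radii
  smooth the scores but mix classes near boundaries.
* **Cross-class normalization** (scores sum to 1) was chosen over
  per-class scaling: it keeps every score well below 1, matching the
  intuition that even the best class hosts the plant in a minority of
  windows, and makes scores comparable across maps.
* **Edge classes**: selected classes are split into interior and edge
  variants before scoring (the plant favours wood margins and field
  borders). A source-class cell within `width` cells (Chebyshev, default
  1) of a different class is relabelled `edge of <class>`. Derived edge
  codes count as their source for the boundary test, making the
  operation idempotent.
* **Spatial k-fold** (default k = 5 contiguous strips, remainder rows to
  the last strip): each fold drops one strip's presences and scores on
  the rest; the reported score is the fold mean, the sd (ddof = 1) is a
  spatial-stability diagnostic. Empty folds are skipped with a warning.

## Boyce-index validation

With the suitability range cut into classes (or overlapping moving
windows), `P_i` is the fraction of presences and `E_i` the fraction of
cells falling in class `i`; the index is the Spearman rank correlation
(average ranks on ties) between `F_i = P_i/E_i` and the class rank. The
continuous variant slides `n_eval = 100` windows of width one tenth of
the observed range (both defaults configurable); windows covering no
cells are dropped and at least three must remain. The evaluation
protocol estimates scores on the upper strip of the map and computes the
index on the lower strip, so the validation ground is spatially disjoint
from the training ground. The index is invariant under strictly
increasing transforms of the suitability values (rank-based), and the
classwise index equals the Spearman correlation of the fixed-bin
predicted-to-expected curve by construction.

## Spread dynamics and discretization

Space: 5-point Laplacian with zero-flux boundaries via ghost-cell
reflection — pure diffusion then conserves the total population exactly
(to solver round-off), and the stencil is second order. The PDE solver
requires nodata-free layers; fill gaps before simulating.

Time: a splitting of reaction and diffusion. The reaction (logistic
growth minus Holling-II removal) is advanced with an explicit Heun step
(second order), then the diffusion propagator is applied:

* `imex` (default): `(I − dt·D·L)⁻¹` by sparse LU, factorized once per
  `(shape, D·dt/h²)` and cached — unconditionally stable;
* `lawson`: `exp(dt·D·L)` applied exactly in the DCT-II eigenbasis of
  the Neumann Laplacian — an exponential integrator, exact in time for
  pure diffusion.

Both schemes pass the same convergence tests; they agree to the
splitting error, not bitwise. Defaults: `dt = 0.02` yr for plain
simulation (`0.05` in the control sweep, where each iteration runs the
PDE twice). Negative values produced by the explicit reaction are
clipped to zero with the clipped mass logged; non-finite values abort
with a diagnostic. Density is carried in carrying-capacity units
(`k = 1` by default), so the initial state "presence × suitability" puts
every occupied cell at its local logistic equilibrium; any `k > 0` is
supported.

Parameter defaults are placeholders pending a species-specific
calibration and are meant to be overridden from the config file:
`D = 100` m²/yr (stand expansion of tens of metres per decade),
`r = 0.5` /yr, `k = 1`, `μ = 1` per effort-year, `τ = 0.1` yr.

## Optimal control

The objective discounts (rate `δ`) a quadratic effort cost `α E²`, a
cubic budget penalty `β E³/B³` (the budget bound `E ≤ B` is enforced
only through this penalty — no hard projection), the running damage
`γ u`, and the terminal population `θ u(T)`. Defaults (`α = β = 1`,
`γ = θ = 10`, `δ = 0.05`, `B = 2`, `T = 5`) are likewise placeholders:
damage weights large enough that inaction is never optimal on an
infested landscape.

The costate is implemented as the **exact discrete adjoint** of the
forward scheme: the backward recursion reuses the (symmetric) diffusion
propagator and the pointwise Jacobian of the Heun reaction update, with
terminal condition `λ(T) = θ e^{−δT}` plus the terminal quadrature weight
of the running damage. This is a consistent discretization of the
continuous costate PDE

```
−∂λ/∂t = D Δλ + λ [r ρ − 2 r u/k − μE/(1 + τμu)²] + γ e^{−δt}
```

but, unlike an independently discretized costate, it reproduces
finite-difference gradients of the discrete objective to ~1e−8 relative
— the mandated gradient check is the primary correctness test of the
derivation, so any slip is caught mechanically.

The sweep iterates: forward solve, backward solve, pointwise stationary
effort from `2α e^{−δt}E + 3β e^{−δt}E²/B³ = λ μu/(1 + τμu)` (zero when
the right side is non-positive; the positive quadratic root otherwise),
then the damped update `E ← (1−ω)E + ωE*` with `ω = 0.5`. An update that
would increase the objective is retried with halved `ω`; stagnation
stops the sweep, so the accepted-objective history is non-increasing by
construction. Convergence is declared at max relative effort change
below `tol = 1e−4` (max 100 iterations). The effort at the final time
node is fixed at zero — it never acts on the dynamics and only costs.
An optional boolean mask confines effort to a management area (e.g. a
park polygon); effort is forced to zero outside.

## Uncertainty propagation

Per-class suitability scores are modelled as independent Gaussians
(truncated at 0 when realized into maps). For each input, orthonormal
polynomials are built from its raw moments via the Cholesky factor of
the Hankel moment matrix — Gaussian inputs reproduce probabilists'
Hermite, uniform inputs Legendre — and its 3-point Gauss rule follows
from the Golub–Welsch construction. The multivariate basis is the
total-degree-`p` product set (`p = 2` default; `(n+p)!/(n!p!)` terms),
and the collocation grid is the level-1 Smolyak combination of the
1-point (mean) and 3-point rules: `2n + 1` nodes for `n` inputs.

Coefficients are fitted by the sparse pseudo-spectral method: the
discrete projection `a_k = Σ w u Ψ_k / Σ w Ψ_k²` is applied per tensor
term of the combination, each term contributing only the modes it
integrates exactly. Projecting directly on the union node weights
aliases cross-term variance into univariate modes (we measured variance
7.5 instead of the exact 6 on an additive quadratic); the per-term
construction is exact for additive polynomials through degree 2.
Mixed modes (two or more nonzero indices) are invisible to a level-1
grid — every node varies one input at a time — and their coefficients
are zero: the expansion captures additive effects and no interactions,
the price of `2n + 1` instead of `3ⁿ` model runs. The mean map is `a_0`
and the variance map `Σ_{k≥1} a_k²` (orthonormal basis). On the test
fixture, expansion mean and sd at two years agree with a 500-sample
Monte-Carlo estimate within 3 standard errors on every cell, indicating
interactions are negligible there; inputs with zero sd are treated as
certain.

## Synthetic scenarios: what they show and what they do not

The generator produces a patchy categorical landscape (white noise
smoothed to correlation length `blob_scale`, quantile-sliced into
equal-area classes) and independent Bernoulli presence with probability
`rate · score/max(score)` per cell. Defaults — 200×200 cells of 20 m, 8
classes with suitabilities ramped 0.05–0.9, `blob_scale = 5`, occupancy
rate 0.05 for the top class — give roughly a thousand presences, enough
for stable frequency estimation; smaller fixtures (20×20 for the control
sweep, 40×40 for the Monte-Carlo comparison, 100×100 for Boyce
behaviour) keep the default test run and the acceptance script within
seconds to minutes on one CPU. All randomness flows through explicit
seeds; rasters are bit-identical across reruns.

Equal-area classes make the neighbourhood-frequency estimator's ranking
coincide with the true suitability ranking; on real maps with very
unequal class areas the raw frequencies conflate area with suitability,
and the recovery results here do not speak to that bias. Bernoulli
presence also ignores the clumped growth of a root-sprouting plant —
clumping would strengthen the frequency signal, not weaken it — and the
generator does not emulate classification error in the presence map.

## Known limitations

* No advection (wind/water transport), seed-bank dormancy, or stochastic
  demography in the dynamics.
* The budget enters only as a soft penalty; realized effort can exceed
  `B` where the shadow price is extreme.
* The forward–backward sweep finds a stationary policy; the problem is
  non-convex and global optimality is not guaranteed (the damped,
  monotone iteration has always converged to the same policy from the
  zero start in our tests).
* Level-1 collocation ignores interaction effects between uncertain
  scores (see above); raise the level/grid if interactions matter.
* No reprojection or CRS handling: all layers must already share a grid.
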