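# Methods

This note records what `tlrec` computes, the estimators and numerical
choices behind it, and what the test suite's synthetic benchmarks do and do
not establish about real data.

## Recurrence sets

All indices start from the same construction. For a trajectory of `N`
states sampled every `dt` and a reference index `i`, the observable
`g(t) = −log dist(x(t), x(i))` is computed against every state (Euclidean
distance by default; cosine and standardized-Euclidean are registered, and
`register_distance` accepts user metrics). Candidates within the Theiler
window `|t − i| ≤ w` are removed so that the sampling of a single
trajectory pass cannot masquerade as independent neighbours; `g(i) = +∞` by
convention and an exact duplicate state also yields `+∞` with a warning.

**Rank-based selection.** With a candidate pool of size `M`, the recurrence
count is fixed at `m = max(1, floor((1−q)·M))` and the `m` largest `g`
values are taken; the threshold `s` is reported as the largest non-selected
value, so every exceedance `u = g − s` is strictly positive except in an
explicitly flagged all-ties case. A fixed count — rather than an
interpolated sample quantile — is what makes the reference set and the
forward-reference set exactly equal in size on finite data, which the
intersection index below requires. Ties are broken toward the smaller time
index, deterministically. The floor is evaluated with a `1e-9` guard
because `(1−q)·M` is not exactly representable in binary for common `q`.

## Time-lagged recurrence α

For horizon `L` steps, two recurrence sets are built with the same
parameters: one for `x(i)`, one for `x(i+L)`. Their candidate pools are
matched: the reference set draws from `{t : 0 ≤ t < N, 0 ≤ t+L < N}` and
the forward set from the image of that pool shifted by `L`. This matters:
if both sets drew from the *same* pool, shifted recurrence times landing in
the last `|L|` indices could never match, biasing α low — negligibly at
`N = 10⁵` and `L ≤ 440`, badly at small `N`. With matched pools the index
is exactly invariant under rigid motions of the orbit (a sampled circle
gives α = 1 at every commensurate horizon, which the suite asserts), and
time reversal is an exact duality: α at `−L` equals forward α at the
mirrored index of the reversed trajectory.

Because the two pools can still lose different numbers of points to their
Theiler windows near the trajectory edges, the common count `m` is fixed
from the smaller post-Theiler pool, making `|R_i| = |R_{i+L}| = Nn` exact
for every reference. α is then an integer-index set intersection, never a
re-thresholding of distances, so the set form and the conditional
probability form coincide exactly — the suite asserts bitwise equality of
the two code paths on randomized trajectories.

`RecurrenceParams.quantile_pool` exposes whether `m` is derived from the
pool before (`"full"`) or after (`"post-theiler"`, default) Theiler
exclusion; on the Lorenz benchmark the difference is below one recurrence
in a thousand.

## Local dimension and persistence

Exceedances of a high quantile of `g` follow the exponential (shape-zero
generalized Pareto) law for well-behaved systems, with state-dependent
scale `σ(ζ)`. The scale is estimated by its closed-form maximum-likelihood
value, the sample mean of the exceedances, and the local dimension is
`d = 1/σ`; no general GPD shape fit is attempted. Sampling checks: 10⁴
exponential draws of scale 1/3 recover `d = 3 ± 0.1`, and iid samples of a
2-D disc recover mean `d ∈ [1.85, 2.15]`.

The extremal index θ is estimated by the Süveges maximum-likelihood
formula on inter-recurrence gaps `T`: with `S = T − 1`, `p = 1 − q`,
`N_c = #{S > 0}` and `K = Σ p·S`,

    θ = (K + (Nn−1) + N_c − sqrt((K + (Nn−1) + N_c)² − 8·N_c·K)) / (2K),

clamped to `[1/Nn, 1]`; `K = 0` (one unbroken run of consecutive
recurrences) falls back to the one-cluster limit `θ = 1/Nn`. Persistence is
`Θ = 1/θ` steps, the mean residence time near the state. Synthetic
processes with exceedances in runs of length `k` recover `θ ≈ 1/k`;
isolated exceedances give `θ > 0.95`.

## Real-time analog proxy

The direct index needs `x(i+L)`, so for a current, unprecedented state the
package averages the cached α of its `Na` nearest past analogues. Analogues
are de-duplicated Theiler-style (within any window of `w` steps only the
closest candidate is kept) so one lingering pass cannot supply all `Na`
votes. Default `Na` mirrors the recurrence count implied by `q`, and may be
overridden. On held-out Lorenz-63 states the proxy's Spearman rank
correlation with the directly computed α is ≈ 0.98.

## Simulators and the Lyapunov time

The generators exist so that every analysis is reproducible from nothing,
at the conditions the benchmark protocol prescribes: Lorenz-63 at the
classical chaotic parameters (σ=10, ρ=28, β=8/3), `dt = 5·10⁻³`, 10⁵
recorded steps after a 10⁴-step discarded transient. Integration is
fixed-step RK4 (the suite asserts 4th-order step-halving convergence);
Rössler defaults to (a, b, c) = (0.2, 0.2, 5.7) and the double pendulum to
unit masses and lengths with g = 9.81 in Hamiltonian two-angle/two-momentum
form (energy drift < 10⁻⁶ relative over 2·10⁴ steps at dt = 10⁻³). The
diffusive Lorenz variant uses Euler–Maruyama with seeded additive isotropic
noise; its amplitude is a free parameter (default 0.5) chosen to perturb
without destroying the attractor's geometry, and the suite asserts only the
direction of its effect (mean α not above the deterministic run's).

The maximum Lyapunov exponent uses the Benettin renormalisation scheme in
its shadow-perturbation form — a second trajectory offset by `d0 = 10⁻⁸`,
rescaled every 10 steps — because it needs nothing but the vector field;
the first 10% of renormalisation events are excluded while the
perturbation aligns with the most unstable direction, and a standard error
is reported over 20 consecutive blocks. On bounded attractors the default
`d0` is safe; on test systems with unbounded growth `d0` must dominate the
rounding noise of the reference state (the suite's saddle test uses
`d0 = 10⁻⁶`). For Lorenz-63 this yields λ_max ≈ 0.90, Lyapunov time
`η_ℓ = 1/λ_max ≈ 1.10−1.11`, stable to ±5% across seeds. Horizons in
Lyapunov units convert to steps by `L = round(η·η_ℓ/dt)`; with `η_ℓ = 1.1`
the benchmark grid [0.05, 0.1, 0.2, 1, 2]·η_ℓ is exactly [11, 22, 44, 220,
440] steps.

## Phase-space stratification

K-means (scikit-learn; k-means++, best of 10 seeded restarts) partitions
the states; per-cluster mean-α curves over the horizon grid are summarised
by their trapezoidal AUC, computed on the Lyapunov-unit axis when `η_ℓ` is
supplied and on raw steps otherwise, and also reported normalized by the
axis span. `k = 7` is the benchmark default for Lorenz-63; cluster numbering
is arbitrary, so the lobe-switching cluster is identified geometrically as
the centroid minimising `|x| + |y|`. Distribution modes are the centre of
the most populated 0.05-wide bin, ties resolved toward the lower bin.

## Benchmark sizes and determinism

The benchmark analyses subsample 2000 reference states (seeded, uniform,
without replacement) from the ~10⁵ valid indices; the full sweep is
available by passing `refs="all"`. Every stochastic step takes an explicit
seed, and the CLI derives per-stage seeds from one global seed by a fixed
hash, so partial re-runs are byte-reproducible.

## What the synthetic benchmarks do not show

The generators emulate clean, uniformly sampled, stationary, low- to
moderate-dimensional dynamics. They do not emulate observational noise
(beyond the additive-diffusion variant), missing samples, nonstationarity,
or the very high ambient dimensions of gridded geophysical fields — for
those, rows of flattened maps can be fed through the same machinery, but
sampling density per neighbourhood, not dimension itself, is then the
limiting factor. Passing tests therefore establish correctness of the
estimators and their behaviour under the stated study conditions, not
performance on any particular observational dataset.

One benchmark expectation is not met and is deliberately left failing
rather than loosened: at the longest benchmark horizon (2 Lyapunov times,
`L = 440`) the mode of the α histogram over Lorenz-63 states computes to
0.075 — stable across reference subsamples and across every definitional
knob the package exposes, and confirmed by an independent brute-force
implementation of the definitions — while the benchmark band expects it
within [0.1, 0.3] around a nominal ≈ 0.2. The computed distribution is
consistent in magnitude with the theoretical exp(−Σλ⁺·η) ≈ 0.135 at this
horizon, and at `L = 220` the distribution's mean is 0.21 with mode bin
0.125; the nominal value appears to describe the two longest horizons
jointly rather than `L = 440` alone.

## Known limitations

- O(|refs|·|horizons|·N) exact distance evaluations; no approximate
  nearest-neighbour index. At `N = 10⁵`, 2000 references × 5 horizons runs
  in about a minute; `refs="all"` at that size is ~50× longer.
- Uniform sampling is assumed throughout; irregular time steps and missing
  values are rejected, not imputed.
- `w` must be chosen by the user (50 steps for the Lorenz benchmark; one
  decorrelation time is the usual heuristic). Too small a window inflates α
  with same-pass neighbours; the package does not auto-detect this.
- The exponential (shape-zero) exceedance model is assumed, not tested
  per-state; heavy-tailed deviations would bias `d`.
- θ's Süveges estimator assumes the standard peaks-over-threshold mixture
  for gap times; strongly non-stationary recurrence streams violate it.
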