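# Methods

## The single-progenitor model

The SP model treats the basal layer of a squamous epithelium as a mixture
of progenitor (A) and differentiating (B) cells. Each A cell divides at
rate λ (per week); the division outcome is AA with probability r, AB with
1 − 2r, BB with r (0 < r ≤ 0.5). Equal AA and BB probabilities make the
A-population a *critical* branching process: E[n_A(t)] = n_A(0), clones go
extinct almost surely, and surviving clones grow linearly in mean — the
signature behaviour seen in lineage tracing. Each B cell stratifies out of
the basal layer at rate Γ. Homeostasis (constant basal cell number with a
progenitor fraction ρ) fixes Γ = ρλ/(1−ρ), so the model is fully specified
by (λ, r, ρ). Suprabasal shedding (rate μ) never affects basal clone
sizes; the parameter is carried on `SPParameters` for completeness but no
computation uses it, and it is unset by default.

Unit conventions: all rates are per week internally; timepoints arrive in
days (the lineage-tracing convention, default grid 3, 10, 21, 42, 84, 180,
365 days) and are divided by 7 exactly once at ingest.

A clone is founded by a single labelled A cell by default, on the
assumption that induction marks a cycling cell. Because the literature is
not explicit on this point, `SimulationConfig(random_initial_basal=True)`
instead draws the founder as A with probability ρ and B otherwise.

## Simulators

The Markovian engine is a plain Gillespie simulation on (n_A, n_B) with
per-cell rates λ (division) and Γ (stratification). The non-Markovian
engine replaces the exponential division wait with a per-cell
Gamma(k, 1/(λk)) draw scheduled at the cell's birth, keeping the mean
division time at 1/λ for every shape k; stratification stays exponential
(only the cell-cycle law is known to deviate from memorylessness). The
event queue is a per-clone array of pending per-cell event times; clones
are independent, so the state never exceeds a few thousand cells and a
linear next-event scan is faster than a heap at these sizes. With k = 1
the Gamma engine reproduces the Markov chain in distribution, which is
tested by two-sample KS at every timepoint. Both kernels are
numba-compiled and bit-reproducible given a seed.

The Gamma shape used in examples and tests is k = 8 (coefficient of
variation ≈ 0.35, a pronounced refractory period, in the range reported
by histone-dilution and live-imaging studies). It is an author choice —
the shape is an input measured by orthogonal experiments, not something
the package fits — and every function that needs it takes it explicitly.

## Exact clone-size probabilities

Because the SP model is a two-type branching process, the generating
function F(z, t) = E[z^(n_A+n_B)] from one A cell satisfies

    dF_A/dt = λ ( r F_A² + (1−2r) F_A F_B + r F_B² − F_A ),  F_A(z,0) = z,
    F_B(z, t) = 1 + (z − 1) e^(−Γt),

where the B-equation is closed-form (a B cell never divides). The engine
integrates this scalar complex Riccati ODE at M = 2·n_max points on the
unit circle (DOP853, rtol 1e-10, atol 1e-12, all requested timepoints in
one pass) and recovers P_n(t) by forward DFT. This evaluates the exact
solution of the branching process by quadrature; the classical
closed-form of the same solution in terms of Whittaker/confluent
hypergeometric functions is mathematically equivalent but numerically
fragile over a whole (r, ρ) grid, so the ODE route is the normative
implementation here. Default n_max is 128 (512 where late-time tails
matter); mass beyond n_max is reported as `truncated_mass`, and
survival conditioning divides by 1 − P_0 rather than renormalizing over
the stored support so that true tail mass is not redistributed.

The independent cross-check is a direct integration of the forward master
equation on a truncated (n_A, n_B) lattice via the sparse matrix
exponential (`expm_multiply`, sequential propagation between timepoints).
Truncation is diagnosed a posteriori: off-lattice flux leaves the system,
so 1 − ΣP measures the leakage, and the integrator refuses results with
leakage above 1e-8. Caps are chosen from the geometric tail of the
critical A-process (surviving n_A is approximately geometric with mean
1 + λrt). The two exact engines agree to better than 1e-6 (in practice
~1e-12), and both agree with Gillespie sampling within Monte-Carlo
tolerances — a three-way consistency argument in which each route has
independent failure modes.

Lattice cost grows roughly as (λrt)² states × λt steps, so the
master-equation check is run at the full 3 × 3 (r, ρ) benchmark grid for
t ≤ 84 days and extended to 365 days at the smallest r; the 365-day
column for larger r is covered by the analytic-vs-Gillespie comparison
(N = 1e5 clones). These problem sizes are the package's desk-scale
choices and are encoded in the acceptance tests.

## Maximum likelihood

ℓ(θ; x) = Σ_t Σ_n x_n(t) log p_n(t, θ) over a uniform open-interval grid:
r_i = 0.5·i/n_r (i = 1..n_r, upper bound 0.5 included, matching the
closed bound on r), ρ_j = j/(n_ρ+1). The default grid is 49 × 49 for the
analytic route and 19 × 19 for the simulation route. λ is fixed; a fit of
λ is deliberately not offered. Observed tables contain surviving clones,
so conditioned PMFs (p_n/(1−P_0)) are the default; the flag is explicit
because the conditioning convention of published fits is not stated.

An observed size with zero estimated probability (a sampling zero of a
simulation-estimated PMF) contributes a documented sentinel of −1000 per
clone instead of −∞, keeping the grid ranking total; affected cells are
counted in the surface metadata. This sentinel is also why
simulation-based fits need simulations to outnumber observations: rare
observed sizes otherwise dominate the surface through the penalty, which
is precisely the sampling pathology that makes the simulation-MLE route
unreliable at realistic budgets.

Confidence intervals: published fits of this model rarely state their CI
construction, so the package records its own — exponentiate the
log-likelihood relative to its maximum, normalize over the grid,
marginalize each parameter, and read equal-tailed quantiles off the
discrete marginal. Degenerate surfaces (all mass in one cell) yield
zero-width intervals with a warning. These intervals are comparable
between fits made by this package but should not be expected to
reproduce any particular published interval exactly.

## SMC-ABC

Priors are independent uniforms r ~ U(0, 0.5), ρ ~ U(0, 1); λ and the
Gamma shape are supplied, not fitted. The distance is the sum over
timepoints of the two-sample KS statistic between simulated and observed
surviving clone sizes, with mice pooled within a timepoint (per-mouse
averaging is not described in the protocols this follows; pooling is
recorded in the output metadata). Defaults follow the full protocol:
10 populations × 500 particles × 1000 simulated clones per candidate.
Generation 1 accepts prior draws outright; each later generation
resamples by weight, perturbs with a Gaussian kernel whose covariance is
twice the weighted particle covariance, rejects proposals outside the
prior support, and accepts at the median of the previous generation's
accepted distances (tolerances therefore strictly decrease). Weights use
the standard SMC importance correction (flat prior over kernel mixture).
If acceptance falls below 1e-3 the loop stops early with a warning and a
partial population — continuing past that point risks overfitting the
noise in the observed distributions. The full run is deterministic given
the config seed.

Summaries are weighted medians and equal-tailed credible intervals, plus
a weighted Gaussian KDE over (r, ρ) for plotting; effective sample sizes
below 10 trigger a warning.

## Synthetic cohorts

A cohort mirrors a sacrifice design: `mice_per_timepoint × n_timepoints`
animals, each contributing exactly one timepoint. Per mouse, (λ, r, ρ)
are drawn from independent normals (rejection-resampled into the valid
domain), `simulated_clones_per_mouse` clones are simulated to the
sacrifice time, survivors are kept, and `clones_per_mouse` of them are
subsampled without replacement into the observation table (`None` keeps
all survivors; a shortfall keeps all with a logged warning). Ground truth
(per-mouse parameters and seeds) lives in a separate ledger that
round-trips through CSV bit-exactly (%.17g) and never appears in the
observation table.

Two stock designs reproduce the standard validation conditions:

- `large_sample_design`: one parameter set, exponential cycles, ~1e5
  total clones over the 7 standard timepoints, all survivors kept — the
  regime where grid MLE recovers (r, ρ) to within one grid cell.
- the realistic-noise design used in the tests: 21 mice (3 per
  timepoint), 1e4 simulated clones each (all survivors kept, the reading
  most consistent with the stated simulation protocol), Gamma(8) cycles,
  per-mouse draws λ = 2.9 ± 0.1, r = 0.09 ± 0.01, ρ = 0.7 ± 0.05 — the
  regime where the exponential-engine MLE excludes the true r while
  SMC-ABC brackets it.

The experiment-design study uses 5 mice per timepoint with draws
λ = 2.85 ± 0.15, r = 0.08 ± 0.02, ρ = 0.7 ± 0.1 and exponential cycles;
`subset_timepoints(..., rebalance=True)` redistributes the fixed animal
budget over a timepoint subset (regenerating mice from the stored design
with a derived seed). On a seeded cohort, early-only ({3, 10, 21} d) and
late-only ({84, 180, 365} d) schedules fail to bracket the generating
parameters while {3, 42, 365} d brackets both — the basis for the
recommendation to spread few timepoints across the whole time course.

What the generator does *not* emulate: induction efficiency, clone
merging/fragmentation at high labelling density, spatial interactions
between clones, and suprabasal counts. Passing tests therefore validate
the inference machinery under the SP model's own assumptions plus stated
noise, not the SP model itself against tissue.

## Numerical choices and limitations

- Generating-function ODE: DOP853 with rtol 1e-10 / atol 1e-12; PMF
  entries are clipped of O(atol) negative round-off, and anything below
  −1e-7 raises rather than propagating silently. Results are cached per
  (λ, r, ρ, timepoints, n_max), which makes per-timepoint decompositions
  and repeated fits on shared timepoints nearly free.
- Master equation: leakage tolerance 1e-8, auto-caps from the geometric
  tail bound with floors of 25 states per axis.
- Grid likelihoods: −inf for failed grid points (masked and counted, the
  grid is never aborted); surfaces are summable, and the per-timepoint
  decomposition is exact by construction.
- KS statistic: exact sup-norm over the merged step points (validated
  against brute force and scipy).
- Determinism: every stochastic entry point takes a seed; kernels seed
  numba's RNG once per call. Identical config + seed gives identical
  output on a given platform.
- Known limitations: the analytic engine requires exponential cycles (no
  closed form exists otherwise — use the simulation route or ABC); the
  master-equation oracle is impractical for λrt ≳ 10 at leakage 1e-8;
  grid MLE inherits grid resolution (intervals are quantized to nodes);
  ABC tolerances below the noise floor of the observed data trigger the
  early-stop rather than sharpening further.
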