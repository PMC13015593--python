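# Methods

## Model

For one output neuron y ∈ {0,1} and inputs x ∈ {0,1}ⁿ observed in L time
bins of width Δt, the package fits the distribution of maximum entropy
consistent with the empirical mean ⟨y⟩ and pairwise correlations ⟨y xᵢ⟩,
where ⟨·⟩ denotes the per-bin sample average. That distribution is the
logistic neuron P(y=1|x) = σ(b + Σ wᵢxᵢ); b and wᵢ are the Lagrange
multipliers of the constraints, in natural-log-odds units. The model is
conditional throughout — the input distribution is always the empirical one,
never modeled. Stationarity within the raster is assumed; duplicate time
bins are naturally weighted by multiplicity.

Entropies are evaluated from the multiplier identity
S_dir = ⟨ln Z(x)⟩ − b⟨y⟩ − Σ wᵢ⟨y xᵢ⟩ (nats, divided by ln 2 for bits);
when the constraints hold this equals the average conditional entropy
⟨H₂(p(x))⟩. S_tot = H₂(⟨y⟩) with the 0·log 0 = 0 convention, so degenerate
outputs (⟨y⟩ ∈ {0,1}) give S_tot = 0. All reported entropies and
informations are in bits; rates may be displayed per second by dividing by
Δt, but every statistical comparison is done on per-bin probabilities, where
Δt cancels.

An exact analytic distribution can stand in for samples everywhere: a
`WeightedRaster` stores distinct configurations with probability weights and
every empirical average becomes a weighted average.

## Fitting

The multipliers minimize the KL divergence between data and model,
equivalently the convex dual F(b,w) = ⟨ln Z⟩ − b⟨y⟩ − Σ wᵢ⟨y xᵢ⟩, whose
gradient components are exactly the constraint violations ⟨y⟩_P − ⟨y⟩ and
⟨y xᵢ⟩_P − ⟨y xᵢ⟩. Steps are damped Newton: the Hessian of ⟨ln Z⟩ is the
(n+1)×(n+1) model covariance of the constraints, cheap at the input counts
this package targets, and a backtracking line search keeps descent monotone.
Plain first-order updates scaled by the inverse *diagonal* curvature were
tried first and retained only as the fallback for numerically singular
Hessians: their linear convergence rate is governed by the correlations
between constraints and becomes impractically slow precisely on the
correlated instances one cares about. Near the optimum, where the dual
decrease falls below float resolution, a full Newton step is accepted
whenever it still shrinks the worst violation.

Defaults, with rationale:

- **Initialization** b = logit(⟨y⟩) clipped, w = 0 — satisfies the mean
  constraint immediately; greedy refits warm-start from the previous step's
  parameters with the new weight at 0.
- **Tolerance** min(10⁻⁶, 0.1·minᵢ σ_{⟨y xᵢ⟩}) on the worst violation — an
  order of magnitude below the Poisson error bars, so a fitted correlation
  can never fail the 2σ prediction test; `max_iters` 10⁵ (Newton uses a few
  dozen). Non-convergence returns the model flagged, it does not raise.
- **Caps** |b|, |wᵢ| ≤ 60 — linearly separable data (e.g. a noiseless AND
  gate) drive multipliers to infinity; the box keeps them finite. The cap
  must exceed the *sum* of weights relevant to a silent configuration
  (the deterministic AND optimum has b ≈ −1.5·w), and 60 leaves constraint
  violations ~10⁻⁹ and per-configuration probabilities within 10⁻³ of the
  deterministic table while keeping ln Z well-conditioned.
- ln Z is evaluated as softplus via `logaddexp`; probabilities via `expit`.

`brute_force_maxent` solves the same dual by enumeration (≤ 2¹⁰
configurations) with scipy's L-BFGS-B plus a projected-Newton polish to the
10⁻¹² entropy identity; it is a deliberately separate code path used as the
oracle in tests, never as the fitter.

## Statistics and error bars

The standard deviation of a co-activity rate with count C = L·⟨y xᵢ⟩ is
taken as √max(C,1)/L (Poisson). The max(C,1) floor keeps the 2σ band
strictly positive for rates that are exactly zero, so zero predictions are
never trivially right or wrong by floating-point noise. The same convention
is applied to higher-order and delayed correlations (delayed ones over the
overlapping window of length L−τ, for both measured and predicted values).
For a `WeightedRaster` without an attached sample count, the number of
stored configurations is used as L — deliberately wide error bars, since an
exact distribution has no sampling noise to calibrate against.

Only inputs that co-activate with the output at least once (⟨y xᵢ⟩ > 0) are
eligible: the multiplier of a never-co-active input diverges. A correlation
is called significant when |⟨y xᵢ⟩ − ⟨y⟩⟨xᵢ⟩| > 2σ; no multiple-testing
correction is applied anywhere, matching the framework's stopping rule
semantics.

## Greedy selection and n*

Selection starts from the independent model and adds, at each step, the
candidate whose refit entropy is smallest (`mode="exact"`, O(N) fits per
step) or whose estimated drop is largest (`mode="approx"`, O(1) fits). The
estimate expands S_dir to second order in the candidate's prediction error
Δ = ⟨y x_c⟩ − ⟨y x_c⟩_P:

    ΔS_dir ≈ −Δ² / (2 χ_eff ln 2),
    χ_eff = ⟨x_c p(1−p)⟩ − cᵀ H⁻¹ c,

where c is the model covariance of the new constraint with the enforced
ones and H their curvature. The Schur term matters: without it the drop is
underestimated by roughly a factor 1−⟨x_c⟩ even for independent candidates,
because re-balancing the existing multipliers absorbs part of the error.
When χ_eff < 10⁻¹² (candidate active only where p is saturated) the exact
refit drop is used. Ties break toward the lowest neuron index for
reproducibility.

After each accepted candidate the full model is refit (warm start), and the
stopping rule is evaluated: n* is the first input count at which every
remaining eligible neuron's correlation is predicted within 2σ. Beyond n*
additional inputs fit statistical noise, so n* doubles as the model's
regularizer; no penalty-based regularization is used. The random-input
baseline draws input sets uniformly from the eligible pool, seeded.

## Ablation

Inputs are removed by marginalizing the *fitted* model over their empirical
activity — parameters untouched. With empirical Q this is exactly the
weighted mean of p(ℓ) within each kept-input configuration observed in the
raster. Surviving information is S_tot − Σ_c Q(c) H₂(P̃(y=1|c)); prediction
error is the mean probability assigned to the wrong output state. Curves
remove, per output, a random ⌈f·n⌉-subset of that output's own inputs and
average over outputs and seeded repeats; population-level removal is a thin
variation the caller can express by passing the same removed set to every
model. Configurations unseen when the table was built (possible only on a
held-out raster) fall back to the model's marginal ⟨p⟩.

## Synthetic generators: what they emulate, and what they don't

- **Logic gates** emulate a single stochastic computation: two iid Bernoulli
  inputs, output flipped with probability ε per sample, so S_true = H₂(ε)
  in closed form and AND/OR (linearly separable) versus XOR (purely
  higher-order) span the two extremes of what direct dependencies can
  capture.
- **Planted logistic networks** emulate the fitting and selection problem
  itself: non-output neurons iid Bernoulli, output drawn from the logistic
  form with a sparse planted weight vector. Ground-truth S_true is the
  average conditional entropy under the planted parameters.
- **Ising populations** emulate recurrent dependence: Gibbs samples over
  {0,1} spins (sequential single-site sweeps; defaults burn-in 10³ sweeps,
  thinning 5 sweeps — generous for the few-unit systems generated here),
  where the single-unit conditional is exactly the logistic model with the
  coupling row as weights. 0/1 spins rather than ±1 avoid any
  reparameterization of that identity. The kernel is numba-compiled and
  seeded via the compiled RNG, bit-reproducible given (parameters, seed).

None of these emulate real recordings' slow latent covariates, burstiness,
non-stationarity, imaging noise, or deconvolution artifacts. Passing tests
therefore validate the *machinery* — estimator correctness, selection and
stopping behavior, information accounting — not the empirical claim that any
particular biological population is well described by direct dependencies;
on real data the stopping rule and the 2σ scoring inherit whatever is wrong
with the Poisson error model there.

## Problem sizes and numerical checks in the test suite

The suite runs at desk scale, chosen to finish in about a minute while
leaving comfortable statistical margins: planted networks with N = 10–18
neurons and L = 2·10⁴–10⁵ bins (weight recovery bands ±0.15 at L = 10⁵;
greedy recovery and n* = 3 required in ≥18 of 20 seeds), 100 random weighted
instances with n ≤ 6 for oracle agreement to 10⁻⁶ bits, Ising recovery at
N = 3, L = 2·10⁵ (coupling band ±0.2, Gibbs-vs-Boltzmann total variation
< 0.01), and 2σ self-consistency scoring with 100 subsets per order at
L = 3·10⁴ (fraction unexplained ≤ 0.15 against a ≈5% nominal rate).

## Known limitations

- The fitter's Hessian is dense; for outputs with many hundreds of inputs a
  curvature-free method would be preferable to the O(n²L) step cost.
- Time-delayed and higher-order *constraints* are out of scope by design:
  the model predicts those correlations but never fits them.
- The n* rule tests each remaining correlation marginally at 2σ; with many
  simultaneous tests it is intentionally liberal (no correction), which is
  part of the method's definition rather than an oversight.
- `WeightedRaster` has no time axis, so delayed correlations require sampled
  rasters.
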