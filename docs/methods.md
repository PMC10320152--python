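# Methods

## Surrogate model

The objective is modeled as a zero-mean Gaussian process observed with
i.i.d. Gaussian noise: `yᵢ = f(tᵢ) + εᵢ`, `εᵢ ~ N(0, σ_ε²)`. The prior
covariance is one of the four half-integer/limit Matérn subfamilies
(Exponential ν=1/2, Matern32, Matern52, RBF ν→∞), parameterized by a
single isotropic length scale κ and a variance σ². Distances are plain
Euclidean norms on the normalized domain: every search-space coordinate
is mapped to [0,1] (affinely, or log-affinely for parameters declared
log-scaled, which is the natural choice for positive, order-of-magnitude
spanning demographic parameters such as population sizes and times).
Per-dimension (anisotropic) length scales are deliberately not offered:
with the small evaluation counts this optimizer targets, a shared κ on
normalized inputs is better identified, and it keeps the hyperparameter
problem three-dimensional.

Observations are centered and scaled (sample SD, ddof=1) before fitting;
a single observation or numerically constant data fall back to scale 1.
The (center, scale) pair is recorded on the fitted model and inverted at
prediction time, which keeps the zero-mean prior assumption reasonable on
the standardized scale.

### Hyperparameter fitting

`(log κ, log σ², log σ_ε²)` are fitted by maximizing the log marginal
likelihood with L-BFGS-B and analytic gradients
(`∂LML/∂θ = ½ tr((ααᵀ − K⁻¹) ∂K/∂θ)`), inside the box
κ ∈ [10⁻³, 10³], σ² ∈ [10⁻⁴, 10⁴], σ_ε² ∈ [10⁻⁸, 10⁻¹] (normalized
inputs, standardized observations). One start is a fixed heuristic
(κ=0.3, σ²=1, σ_ε²=10⁻⁴ — a moderately wiggly function on the unit cube);
the remaining starts are log-uniform in the box. `fit_hyperparameters`
defaults to 10 random restarts; the optimization pipeline uses 5 per
iteration, a cost/robustness trade-off that works because the fit is
repeated from scratch at every iteration, so an occasional local-optimum
miss is corrected one evaluation later. The noise variance is always
optimized, never clamped to zero, even for deterministic objectives — it
absorbs whatever structure the GP cannot represent; its lower bound 10⁻⁸
is a numerical floor, not a modeling statement.

Cholesky factorization of `K + σ_ε² I` uses an escalating diagonal
jitter: starting at 10⁻⁸ × mean diagonal and growing tenfold up to
10⁻² × mean diagonal, after which a numerical error is raised. The jitter
actually used is recorded on the fitted model.

## Acquisitions

EI, PI and LogEI are evaluated in closed form from the posterior
`N(μ(t), σ²(t))`. For LogEI the surrogate is fitted to
`log(y + shift)` where shift = 0 when all observations are positive
(the common case for negative log-likelihoods) and otherwise
`1 − min y`, so the minimum shifted value is exactly 1. The LogEI closed
form is the lognormal partial expectation

```
E[max(0, c − e^G)] = c·Φ(z) − exp(μ + σ²/2)·Φ(z − σ),  z = (ln c − μ)/σ,
```

with c the shifted incumbent; the second term is computed via
`log Φ` to avoid overflow when `exp(μ + σ²/2)` is huge but the adjacent
normal tail is zero. When the predictive σ falls below 10⁻¹² all three
acquisitions reduce to their deterministic limits.

Maximization draws 1,000 uniform candidates on the unit cube, evaluates
the acquisition in one batch, refines the 10 best by bounded L-BFGS-B
(central-difference gradients computed from a single batched posterior
call per iteration, capped at 30 iterations per start — the acquisition
landscape near a good candidate is locally smooth and more iterations buy
nothing), and returns the best point seen; ties break toward the lowest
candidate index. A proposed point within 10⁻⁹ (∞-norm) of an evaluated
point is replaced by the best non-duplicate candidate (repeated inputs
make the Gram matrix singular).

## Prior selection by LOO-CV

For each candidate family, hyperparameters are fitted once on the full
design and held fixed across the n leave-one-out folds; per-fold
refitting would cost O(n⁴) and mostly reshuffles noise at design sizes of
2d. The fold predictions use the rank-one identities
`μᵢ = yᵢ − αᵢ/[K⁻¹]ᵢᵢ`, `σᵢ² = 1/[K⁻¹]ᵢᵢ` (predictive variance includes
the noise term), verified in the tests against naive refits. The score is
the mean log predictive density of the held-out values; the negative
squared-error-plus-variance alternative is implemented for diagnostics
but not used for selection, since it systematically rewards
underestimated predictive variance. Exact score ties fall back to the
fixed order Matern52 > RBF > Matern32 > Exponential (smoother priors
preferred). When the acquisition is LogEI the score is computed on
log-transformed observations, matching what the surrogate will actually
model; the Ensemble, which alternates PI and LogEI, scores on the
untransformed scale. Selection on designs smaller than 4 points is
allowed but logged as low-information.

## The optimization loop

The initial design is 2d points sampled uniformly on the normalized
domain (log-uniform in raw units for log-scaled parameters). The budget
counts objective evaluations including the design. Per iteration: choose
the acquisition (fixed, or the ensemble's fair coin between PI and
LogEI), refit hyperparameters anew, build the acquisition context,
maximize, evaluate, append. The prior family is chosen once, right after
the initial design, and never revisited. Randomness is split into four
independent substreams (design, coin, fits, acquisition) spawned from the
master seed, making entire runs bit-reproducible.

Failed evaluations (exceptions or non-finite values) are recorded with a
failure flag and excluded from the surrogate rather than imputed with a
penalty value, which would corrupt the GP's scale; a run aborts once more
than half of its evaluations have failed. Budgets above 1,000 evaluations
trigger a warning: the per-iteration refit cost grows cubically in the
history size, and the intended operating range is roughly 100–400
evaluations.

`local_polish` runs bounded L-BFGS-B with numerical gradients from the
incumbent, capped at a caller-specified number of objective calls, and
returns the best point it saw (never worse than the start).

## Synthetic objectives

The toy SFS objective is a fixture, not a demographic model. An unfolded
single-population spectrum `ξ₁…ξ_{n−1}` is modeled with independent
Poisson entries with means `μᵢ = θ · i^(−β) · exp(−γ(i−1)/(n−2))`:
θ sets the overall scale (log-scaled in the search space, like a
population-scaled mutation rate), β the power-law frequency decay, γ an
extra suppression of high-frequency alleles. The objective is the exact
Poisson composite negative log-likelihood (constants included,
log-factorials via log-gamma). This reproduces the features of real
SFS likelihood surfaces that matter to the optimizer — an
order-of-magnitude amplitude parameter, strong curvature near the
optimum, mild parameter interactions — but none of the population-genetic
content: no linkage, no multi-population structure, no diffusion or
coalescent expectation. Passing the recovery tests therefore demonstrates
the optimizer's mechanics on an SFS-shaped surface, not the accuracy of
any demographic inference. Spectra round-trip through the
single-population unfolded plain-text dialect (masked monomorphic
corners on disk, corners never entering the likelihood; folded spectra
are rejected).

The deterministic benchmarks (sphere, Rosenbrock, Branin, Hartmann-6)
carry their textbook domains and known optima and serve as desk-scale
stand-ins for expensive likelihoods; an optional artificial per-call
delay emulates expensive evaluation but is excluded from all checks.

## Replication harness

Replicate r of a study derives its seed from
`SeedSequence(master, spawn_key=(r,))`, so each replicate is reproducible
in isolation and unaffected by how many others run. Convergence is
aggregated per evaluation index as median and first/third quartiles
(linear interpolation between order statistics; the convention is
recorded in the export metadata). Wall time is logged per evaluation and
cumulatively but never used as a stopping rule. Exports are one trace CSV
and one summary JSON per replicate plus an aggregated CSV; all content is
deterministic under a fixed seed except the measured wall-time column.

## Problem sizes used in the checks

The verification suite exercises: dense-oracle GP agreement on 50 random
instances (n ≤ 10, d ≤ 5); Monte-Carlo acquisition agreement on random
contexts (≥ 4·10⁵ draws each); LOO identities for every n ≤ 25; all 15
pipeline variants at budget 30 on Branin; Ensemble convergence at budget
60 (20 seeds) on Branin and budget 25 (20 seeds) on a 1-d quadratic; and
toy-SFS recovery at budget 150 with a 200-call polish (10 seeds in the
test suite, 5 in the acceptance script). These sizes were chosen so the
whole suite completes in minutes on a single core while each check still
operates in the regime the method is designed for.

## Known limitations

- Isotropic length scale only; strongly anisotropic objectives are
  modeled suboptimally unless parameters are sensibly scaled/bounded.
- Exact GP inference only: budgets in the thousands become slow, by
  design of the O(n³) refit-per-iteration scheme.
- No discrete or categorical parameters, no batch proposals, no
  wall-clock-budgeted stopping.
- The initial design is uniform on the normalized domain; no
  prior-informed or space-filling (e.g. Latin hypercube) design is
  implemented.
- LogEI assumes the log-transformed observations are well modeled by a
  GP; heavy-tailed or sign-switching objectives rely on the shift rule,
  which is a pragmatic fallback rather than a principled transform.
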