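# Methods

## Balance accounting

Each trial record carries the species, the Ndfa (%, the share of
aboveground N uptake derived from fixation), aboveground N uptake and
seed N (kg ha⁻¹), and optionally a root factor.  The root factor,
`1 + belowground/aboveground N proportion`, converts aboveground uptake
to whole-plant uptake under the assumption that Ndfa is the same above
and below ground.  The two balances are

* PNB = uptake · Ndfa/100 − seed N,
* TNB = uptake · root factor · Ndfa/100 − seed N.

Positive values are net soil N inputs.  Fertilizer, deposition, leaching
and volatilization are deliberately outside this simplified budget.  A
useful identity: PNB = 0 exactly when Ndfa/100 equals the N harvest
index (NHI = seed N / aboveground N), which is what lets independent NHI
surveys inform the prior on the neutral point.  Ndfa is carried in
percent everywhere except inside the Bayesian model, where the neutral
point is a proportion; the `100·θ` factor in the model mean is the only
crossing point.

## Frequentist routes

OLS (via statsmodels) fits `y = β₀ + β₁x + ε` with
`Cov(β̂) = σ̂²(XᵀX)⁻¹`, `σ̂² = RSS/(n−2)`.  The neutral point is
`θ̂ = −β̂₀/β̂₁`.

*Delta method.*  With gradient `g = (−1/β₁, β₀/β₁²)`, the variance is
`gᵀ Cov g` and the interval is Wald-normal, resting on asymptotic
normality of the ratio.  The `nonviable_fraction` diagnostic reports the
normal mass outside [0, 100] %.

*Bootstrap.*  K row-resamples (pairs bootstrap, matching resampling "the
observed data" rather than residuals), each refit in closed form
vectorized across resamples, percentile interval (no BCa or
studentization — the interval is built directly from the K estimates).
Default K = 10,000.  Resamples with constant x or |β̂₁| < 1e−12 have no
intercept ratio; they are excluded from the percentiles and counted in
`n_degenerate` rather than crashing or being silently redrawn.

## Bayesian model

Substituting `β₀ = −β₁θ` gives `y_i = β₁(x_i − 100·θ) + ε_i`, making θ a
first-class parameter with prior support (0, 1).  Priors:

| parameter | prior | default | units / meaning |
|---|---|---|---|
| β₁ | gamma(shape, rate) | (1.6, 0.8) | kg ha⁻¹ per Ndfa %; mean 2, weakly informative, positive by assumption |
| θ  | beta(α, β) | species-specific | proportion of fixed N at neutrality |
| σ  | gamma(shape, rate) | (2.5, 0.05) | residual SD, kg ha⁻¹; mean 50, very diffuse |

Gamma is always (shape, rate); the rate convention is what makes the
default slope-prior mean 1.6/0.8 = 2.

### Prior elicitation

θ_PNB priors are moment matched (`α = m·c`, `β = (1−m)·c`,
`c = m(1−m)/v − 1`) to the sample mean and unbiased (n−1) sample
variance of an independent NHI sample per species; NHI values outside
(0, 1) — symptomatic of severely stressed trials — are rejected.
Infeasible moments (v ≥ m(1−m)) raise an error rather than being
clipped: a silently deformed prior would be worse than a loud failure.
The θ_TNB prior shrinks the PNB mean by the belowground-N fraction and
inflates the variance by 50 % before re-matching, reflecting the weaker
evidence behind root-N allocation.  Reference priors for nine species
and back-derived belowground fractions ship in `ndfa.priors`; the
fractions are derived conveniences (two decimals), not measurements.

### Sampler

An adaptive random-walk Metropolis sampler operates on the unconstrained
coordinates (logit θ, log β₁, log σ) with the log-Jacobian terms
included, so support constraints can never be violated and no proposal
needs rejection for bounds alone.  Updates are coordinate-wise
(three accept/reject steps per iteration); per-coordinate,
per-chain proposal scales adapt during warmup by Robbins–Monro toward a
0.44 acceptance rate (the one-dimensional optimum) with step size
min(1, t^−0.6), and are frozen afterwards, so post-warmup draws target
the exact posterior.  Chains start from independent prior draws
(overdispersed initialization) and advance in lock-step from a single
`SeedSequence(seed)` generator — identical configuration gives
bit-identical draws.

Defaults follow the 4-chain, 20,000-total-iteration, 10,000-warmup
configuration, read as totals across chains (5,000/2,500 per chain); the
reading is configurable since either interpretation is defensible.

Correctness is established two ways: densities are unit-tested against
scipy.stats, and posterior means on a fixed 5-point dataset are checked
against dense Riemann integration of the unnormalized posterior over a
(θ, β₁, σ) grid spanning ±10 posterior SDs at 200 points per axis,
within 3 Monte Carlo standard errors (SE = sd/√ESS).

### Diagnostics and summaries

Split-chain R̂ (each chain halved, classic between/within variance
ratio) is computed in-package and cross-checked against ArviZ's
rank-normalized R̂ in tests; ESS comes from ArviZ.  The pass threshold
is R̂ < 1.05 for every parameter — the diagnostic itself is standard,
the cutoff is this package's choice.  Failure attaches a RuntimeWarning
to the returned samples, never a silent pass.  Posterior marginals are
summarized by pooled mean, variance and (0.025, 0.5, 0.975) quantiles,
and can be moment-matched back to beta/gamma hyperparameters for use as
priors in a later fit.

## Comparing θ_PNB and θ_TNB

Studies (not rows) are randomly partitioned into two halves; the PNB
model is fitted on one and the TNB model on the other, so the two
posteriors are independent.  The difference distribution is formed by
pairing pooled draws after an independent seeded shuffle of each set
(truncating to the shorter), and the decision is zero-inclusion in the
equal-tailed credible interval.  Reversing the direction negates the
quantiles without changing the decision.  The halves are deliberately
*not* matched — the procedure compares independent fits, accepting the
extra between-half variability.

## Synthetic data

`simulate_balance_dataset` draws x ~ uniform(range) and
`y = β₁(x − 100θ) + N(0, σ²)`.  Ndfa design points are uniform because
only ranges and counts are specified for the two regimes; a real
database's design would be clumpier.  The presets encode the two
data-availability regimes:

* **A** (rich): n = 100, Ndfa 6–91 %, truth (θ, β₁, σ) = (0.60, 2.0, 25) —
  the field-pea-like regime where all three methods agree;
* **B** (scarce): n = 10, Ndfa 46–78 %, truth (0.85, 2.4, 24) — a neutral
  point near the support boundary, the white-lupin-like regime where
  frequentist intervals produce nonviable values.

Truth values are explicit config, never hidden constants; σ = 0 is
allowed as the degenerate noiseless case for exact-recovery checks.
`simulate_observations` back-solves seed N = uptake·x/100 − y around
uniformly drawn uptakes (100–250 kg ha⁻¹) and root factors (1.0–1.6),
resampling the uptake when the implied seed N would be negative
(counted, reported), so rebuilding a PNB dataset from the records
reproduces the simulated pairs exactly.  What the generator does *not*
emulate: heteroscedasticity, species mixtures, study-level clustering of
x, measurement error in Ndfa itself.  Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to their violation on real field data.

## Numerical choices and edge cases

* Slopes with |β̂₁| < 1e−12 are treated as zero (no finite intercept).
* Beta/gamma moment matching is exact algebra; round trips hold to
  1e−12 relative error, and comparisons against published two-decimal
  hyperparameter tables use two-decimal tolerance since the printed
  moments are themselves rounded.
* Zero-length datasets are legal for the Bayesian model (posterior =
  prior); fitting operations require n ≥ 3 and non-constant x.
* Delta interval with a zero covariance matrix degenerates to a
  zero-width interval at the point estimate.
* One published species summary (faba bean PNB prior variance) is
  inconsistent with its printed hyperparameters by a factor of ten in
  the variance; the package ships the hyperparameters, which are the
  operative priors, and does not attempt a silent correction.

## Problem sizes

The test suite runs the full default MCMC configuration throughout; the
heavier behavioural checks use 20 seeds (method agreement), 100
replicates (regularization contrast), and 50 replicates (parameter
recovery), sizes at which the binomial/Monte Carlo noise of each check
is comfortably below its tolerance.

## Known limitations

* Coordinate-wise Metropolis mixes more slowly than gradient-based
  samplers; ESS per iteration is modest (roughly 5–10 %), which the
  default iteration count absorbs easily at these problem sizes.
* Each species is fitted separately; no hierarchical pooling.
* The balance model itself is the simplified fixation-vs-removal budget;
  θ estimates inherit that simplification.
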