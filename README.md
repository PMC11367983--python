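# ndfa

Uncertainty quantification for the nitrogen fixation a grain legume needs
to reach a neutral nitrogen balance.

## The problem

Grain legumes acquire part of their nitrogen from symbiotic fixation; the
share of crop N uptake derived from the atmosphere is the **Ndfa** (%).
Whether a legume crop leaves the soil with more or less N than it removes
is summarized by a simplified balance: the **partial N balance**
(PNB = aboveground fixed N − seed N, kg ha⁻¹) or, when root and
rhizodeposition N is included through a *root factor*, the **total N
balance** (TNB).  Regressing the balance on Ndfa,

```
y_i = β₀ + β₁ x_i + ε_i,     ε_i ~ N(0, σ²),
```

the Ndfa at which the expected balance is neutral is the x-intercept

```
θ = −β₀ / β₁,      0 ≤ θ ≤ 100 %.
```

Agronomists routinely report θ as a bare point estimate.  This package
quantifies its uncertainty three ways:

* **delta method** — first-order variance of the ratio, Wald interval;
* **bootstrap** — K pairs-resamples of the data, percentile interval;
* **Bayesian regression** — the model rewritten so θ is a parameter,
  `y_i = β₁(x_i − 100·θ) + ε_i`, with informative priors
  `β₁ ~ gamma(1.6, 0.8)`, `θ ~ beta(α, β)` (species-specific, elicited by
  moment matching from independent N-harvest-index data) and
  `σ ~ gamma(2.5, 0.05)`, fitted by an adaptive random-walk Metropolis
  sampler with split-R̂ convergence checks.

Because the beta prior confines θ to (0, 1), the Bayesian interval can
never contain biologically impossible values (< 0 % or > 100 %) — the
prior acts as a regularizer exactly where scarce, narrow-range data make
delta and bootstrap intervals spill outside the plausible range.  The
package also implements prior elicitation from NHI samples, the TNB prior
adjustment (mean shrunk by the belowground-N share, variance inflated by
50 %), posterior→prior moment matching for sequential updating, and the
posterior-difference test of θ_PNB vs θ_TNB.

Intended users: agronomists and biogeochemists analysing legume N-balance
trials, and anyone needing x-intercept inference with bounded-support
priors.

## Worked example

Simulate the difficult regime — ten observations, Ndfa only spanning
46–78 %, true neutral point at 85 % — and estimate θ by all three
methods, using the white-lupin informative prior:

```bash
ndfa simulate --scenario B --seed 42 --out obs_b.csv
ndfa fit --input obs_b.csv --method all --seed 42 \
         --species "white lupin" --out fit_b.json
```

prints

```
delta     theta =  91.36%  95% interval [71.99, 110.73]
bootstrap theta =  91.36%  95% interval [76.69, 129.37]
bayes     theta =  84.49%  95% interval [78.09, 90.24]
```

The delta and bootstrap intervals extend past 100 % Ndfa — a fixation
level no crop can achieve — while the Bayesian credible interval stays
inside the viable range and brackets the true value (85 %).  With ample,
wide-range data (scenario `A`: n = 100, Ndfa 6–91 %) the three methods
agree to within a few percentage points.

The same workflow from Python:

```python
from ndfa import (assemble_priors, BetaParams, BayesConfig, delta_ci,
                  ols_fit, sample_posterior, scenario_preset,
                  simulate_balance_dataset, theta_credible_estimate)

data = simulate_balance_dataset(scenario_preset("B", seed=42))
priors = assemble_priors(BetaParams(62.52, 14.06), species="white lupin")
samples = sample_posterior(data, priors, BayesConfig(seed=42))
print(theta_credible_estimate(samples))        # Bayesian interval
print(delta_ci(ols_fit(data)))                 # delta-method interval
```

Other subcommands: `ndfa balance` (per-row PNB/TNB from trial records),
`ndfa elicit` (beta priors from NHI tables), `ndfa compare` (θ_PNB vs
θ_TNB posterior difference with the zero-inclusion decision).

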