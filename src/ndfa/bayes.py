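"""Bayesian estimation of the neutral-balance fixation fraction.

Rewriting the balance regression so that the x-intercept is itself a
parameter, the model is

    y_i = beta1 * (x_i - 100 * theta) + eps_i,   eps_i ~ N(0, sigma^2),

with x in Ndfa percent and theta the *proportion* (0-1 scale) of fixed N
at which the expected balance is neutral.  Priors are

    beta1 ~ gamma(shape, rate)   (default 1.6, 0.8),
    theta ~ beta(alpha, beta)    (species-specific, elicited from NHI data),
    sigma ~ gamma(shape, rate)   (default 2.5, 0.05).

Because the beta prior has support (0, 1), every posterior draw of theta
is a biologically viable percentage — the prior regularizes the estimate
where delta-method and bootstrap intervals can spill outside [0, 100].

Sampling uses an adaptive random-walk Metropolis algorithm, updating one
coordinate at a time on the unconstrained scale (logit theta, log beta1,
log sigma) with the appropriate Jacobian correction.  Proposal scales are
tuned during warmup toward a 0.44 acceptance rate and then frozen, so
post-warmup draws target the exact posterior.  All chains advance in
lock-step from a single seeded generator, making runs bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logit

from .balances import BalanceDataset
from .distributions import (
    BetaParams,
    GammaParams,
    MomentPair,
    beta_from_moments,
    gamma_from_moments,
)
from .errors import DomainError, ValidationError
from .frequentist import ThetaEstimate
from .priors import PriorSet

__all__ = [
    "BayesConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "sample_posterior",
    "gelman_rubin",
    "summarize",
    "posterior_hyperparams",
    "theta_credible_estimate",
]

_LOG_2PI = math.log(2.0 * math.pi)
RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class BayesConfig:
    """MCMC run configuration.

    ``iterations_total`` and ``warmup_total`` are totals across chains
    (the defaults — 4 chains, 20,000 iterations with 10,000 warmup — run
    5,000 iterations per chain of which 2,500 are warmup).
    """

    chains: int = 4
    iterations_total: int = 20_000
    warmup_total: int = 10_000
    seed: int = 0
    sampler: str = "random_walk_metropolis"

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError(f"need >= 2 chains, got {self.chains}")
        if not self.warmup_total < self.iterations_total:
            raise ValidationError("warmup_total must be below iterations_total")
        if self.sampler != "random_walk_metropolis":
            raise ValidationError(f"unknown sampler {self.sampler!r}")

    @property
    def iterations_per_chain(self) -> int:
        return self.iterations_total // self.chains

    @property
    def warmup_per_chain(self) -> int:
        return self.warmup_total // self.chains


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-chain Gelman-Rubin diagnostics and effective sample sizes."""

    rhat: dict[str, float]
    ess: dict[str, float]
    passed: bool


@dataclass(frozen=True)
class PosteriorSamples:
    """Post-warmup MCMC draws, one row per chain."""

    theta: np.ndarray  # (chains, draws), proportions in (0, 1)
    beta1: np.ndarray  # (chains, draws), > 0
    sigma: np.ndarray  # (chains, draws), > 0
    config: BayesConfig
    convergence: ConvergenceReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("theta", "beta1", "sigma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 2:
                raise ValidationError(f"{name} draws must be 2-D (chain, draw)")
        if not (self.theta.shape == self.beta1.shape == self.sigma.shape):
            raise ValidationError("parameter draw arrays must share one shape")
        if np.any((self.theta <= 0.0) | (self.theta >= 1.0)):
            raise ValidationError("theta draws must lie strictly in (0, 1)")
        if np.any(self.beta1 <= 0.0) or np.any(self.sigma <= 0.0):
            raise ValidationError("beta1 and sigma draws must be positive")

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains' draws of one parameter, flattened."""
        return np.asarray(getattr(self, name)).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """One row per draw: chain, iteration, theta, beta1, sigma."""
        c, d = self.theta.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d),
                "iteration": np.tile(np.arange(d), c),
                "theta": self.pooled("theta"),
                "beta1": self.pooled("beta1"),
                "sigma": self.pooled("sigma"),
            }
        )


# ---------------------------------------------------------------------------
# densities


def log_likelihood(
    theta: float, beta1: float, sigma: float, data: BalanceDataset
) -> float:
    """Gaussian log likelihood of the reparameterized balance regression.

    Returns -inf (never raises) outside the support 0 < theta < 1,
    beta1 > 0, sigma > 0, so samplers can evaluate freely.  With no data
    the likelihood is identically 1 (log 0.0).
    """
    if not (0.0 < theta < 1.0 and beta1 > 0.0 and sigma > 0.0):
        return -math.inf
    n = data.n
    if n == 0:
        return 0.0
    resid = data.y - beta1 * (data.x - 100.0 * theta)
    return float(
        -0.5 * n * _LOG_2PI - n * math.log(sigma) - 0.5 * np.dot(resid, resid) / sigma**2
    )


def _gamma_logpdf(x: float, p: GammaParams) -> float:
    return (
        p.shape * math.log(p.rate)
        - math.lgamma(p.shape)
        + (p.shape - 1.0) * math.log(x)
        - p.rate * x
    )


def _beta_logpdf(x: float, p: BetaParams) -> float:
    lognorm = (
        math.lgamma(p.alpha + p.beta) - math.lgamma(p.alpha) - math.lgamma(p.beta)
    )
    return lognorm + (p.alpha - 1.0) * math.log(x) + (p.beta - 1.0) * math.log1p(-x)


def log_prior(theta: float, beta1: float, sigma: float, priors: PriorSet) -> float:
    """Joint log prior density; -inf outside the support."""
    if not (0.0 < theta < 1.0 and beta1 > 0.0 and sigma > 0.0):
        return -math.inf
    return (
        _beta_logpdf(theta, priors.theta_prior)
        + _gamma_logpdf(beta1, priors.beta1_prior)
        + _gamma_logpdf(sigma, priors.sigma_prior)
    )


def log_posterior(
    theta: float, beta1: float, sigma: float, data: BalanceDataset, priors: PriorSet
) -> float:
    """Unnormalized log posterior: log likelihood plus log prior."""
    lp = log_prior(theta, beta1, sigma, priors)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(theta, beta1, sigma, data)


# ---------------------------------------------------------------------------
# sampler


def _logp_unconstrained(
    Z: np.ndarray, x: np.ndarray, y: np.ndarray, priors: PriorSet
) -> np.ndarray:
    """Vectorized log target on (logit theta, log beta1, log sigma).

    Includes the change-of-variable Jacobian, so the chain targets the
    posterior of the constrained parameters.  Rows of ``Z`` are chains.
    Non-finite values (e.g. exp overflow) come back as -inf.
    """
    zt, zb, zs = Z[:, 0], Z[:, 1], Z[:, 2]
    with np.errstate(over="ignore", invalid="ignore"):
        theta = expit(zt)
        beta1 = np.exp(zb)
        sigma = np.exp(zs)
        log_th = log_expit(zt)
        log_1mth = log_expit(-zt)

        n = x.size
        if n > 0:
            resid = y[None, :] - beta1[:, None] * (x[None, :] - 100.0 * theta[:, None])
            ll = (
                -0.5 * n * _LOG_2PI
                - n * zs
                - 0.5 * np.einsum("ij,ij->i", resid, resid) / sigma**2
            )
        else:
            ll = np.zeros(Z.shape[0])

        tp = priors.theta_prior
        bp = priors.beta1_prior
        sp = priors.sigma_prior
        # beta prior on theta plus logit Jacobian theta*(1-theta)
        lp = (
            math.lgamma(tp.alpha + tp.beta)
            - math.lgamma(tp.alpha)
            - math.lgamma(tp.beta)
            + tp.alpha * log_th
            + tp.beta * log_1mth
        )
        # gamma priors on beta1/sigma plus log Jacobians exp(z)
        lp += bp.shape * math.log(bp.rate) - math.lgamma(bp.shape) + bp.shape * zb - bp.rate * beta1
        lp += sp.shape * math.log(sp.rate) - math.lgamma(sp.shape) + sp.shape * zs - sp.rate * sigma

        out = ll + lp
    return np.where(np.isfinite(out), out, -np.inf)


def _initial_state(priors: PriorSet, chains: int, rng: np.random.Generator) -> np.ndarray:
    """Overdispersed start: one prior draw per chain, on the free scale."""
    tp, bp, sp = priors.theta_prior, priors.beta1_prior, priors.sigma_prior
    theta0 = np.clip(rng.beta(tp.alpha, tp.beta, size=chains), 1e-6, 1.0 - 1e-6)
    beta10 = np.maximum(rng.gamma(bp.shape, bp.scale, size=chains), 1e-6)
    sigma0 = np.maximum(rng.gamma(sp.shape, sp.scale, size=chains), 1e-6)
    return np.column_stack([logit(theta0), np.log(beta10), np.log(sigma0)])


def sample_posterior(
    data: BalanceDataset, priors: PriorSet, config: BayesConfig | None = None
) -> PosteriorSamples:
    """Draw from the posterior by adaptive random-walk Metropolis.

    Chains start from independent prior draws and advance in lock-step;
    per-coordinate proposal scales adapt only during warmup.  Convergence
    is always checked: if any split-chain R-hat is at or above
    1.05 a warning is raised and recorded on the returned object — never
    silently ignored.
    """
    if config is None:
        config = BayesConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    x = np.asarray(data.x, dtype=float)
    y = np.asarray(data.y, dtype=float)

    C = config.chains
    n_iter = config.iterations_per_chain
    n_warm = config.warmup_per_chain
    n_keep = n_iter - n_warm

    Z = _initial_state(priors, C, rng)
    logp = _logp_unconstrained(Z, x, y, priors)
    scales = np.full((C, 3), 0.5)
    kept = np.empty((C, n_keep, 3))

    target_accept = 0.44  # optimal for one-dimensional random-walk updates
    for t in range(n_iter):
        adapt = t < n_warm
        step = min(1.0, (t + 1) ** -0.6) if adapt else 0.0
        for j in range(3):
            prop = Z.copy()
            prop[:, j] += scales[:, j] * rng.standard_normal(C)
            logp_new = _logp_unconstrained(prop, x, y, priors)
            with np.errstate(over="ignore"):
                acc_prob = np.exp(np.minimum(0.0, logp_new - logp))
            acc_prob = np.where(np.isfinite(logp_new), acc_prob, 0.0)
            accept = rng.random(C) < acc_prob
            Z[accept] = prop[accept]
            logp[accept] = logp_new[accept]
            if adapt:
                scales[:, j] *= np.exp(step * (acc_prob - target_accept))
        if not adapt:
            kept[:, t - n_warm, :] = Z

    samples = PosteriorSamples(
        theta=expit(kept[:, :, 0]),
        beta1=np.exp(kept[:, :, 1]),
        sigma=np.exp(kept[:, :, 2]),
        config=config,
    )
    report = gelman_rubin(samples)
    if not report.passed:
        warnings.warn(
            "MCMC convergence not reached: split R-hat "
            + ", ".join(f"{k}={v:.3f}" for k, v in report.rhat.items()),
            RuntimeWarning,
            stacklevel=2,
        )
    object.__setattr__(samples, "convergence", report)
    return samples


# ---------------------------------------------------------------------------
# diagnostics and summaries


def _split_rhat(chains: np.ndarray) -> float:
    """Classic split-chain potential scale reduction factor.

    Each chain is split in half; R-hat compares the between- and
    within-half-chain variances.  Constant chains return exactly 1.
    """
    c, n = chains.shape
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n_h = halves.shape
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B = n_h * halves.mean(axis=1).var(ddof=1)
    var_hat = (n_h - 1) / n_h * W + B / n_h
    return float(np.sqrt(var_hat / W))


def gelman_rubin(samples: PosteriorSamples) -> ConvergenceReport:
    """Split R-hat and effective sample size for every parameter.

    R-hat uses the between/within-chain variance comparison on split
    chains; the pass flag requires every R-hat below 1.05.  Effective
    sample sizes come from ArviZ's autocorrelation-based estimator.
    """
    import arviz as az

    if samples.n_chains < 2:
        raise ValidationError("Gelman-Rubin needs at least 2 chains")
    if samples.n_draws < 10:
        raise ValidationError("Gelman-Rubin needs at least 10 draws per chain")
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name in ("theta", "beta1", "sigma"):
        arr = getattr(samples, name)
        rhat[name] = _split_rhat(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[name] = float(az.ess(arr))
    passed = all(v < RHAT_THRESHOLD for v in rhat.values())
    return ConvergenceReport(rhat=rhat, ess=ess, passed=passed)


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    """Pooled posterior mean, variance and (0.025, 0.5, 0.975) quantiles."""
    rows = {}
    for name in ("theta", "beta1", "sigma"):
        d = samples.pooled(name)
        q = np.quantile(d, [0.025, 0.5, 0.975])
        rows[name] = {
            "mean": d.mean(),
            "variance": d.var(ddof=1),
            "q2.5": q[0],
            "median": q[1],
            "q97.5": q[2],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def posterior_hyperparams(
    samples: PosteriorSamples,
) -> dict[str, BetaParams | GammaParams]:
    """Moment-match each marginal posterior back to its prior family.

    The result — a beta law for theta and gamma laws for beta1 and sigma —
    can be used directly as priors in a future fit, closing the
    sequential-updating loop.
    """
    out: dict[str, BetaParams | GammaParams] = {}
    for name in ("theta", "beta1", "sigma"):
        d = samples.pooled(name)
        var = d.var(ddof=1)
        if var == 0.0:
            raise DomainError(f"{name} draws are degenerate (zero variance)")
        m = MomentPair(mean=float(d.mean()), variance=float(var))
        out[name] = beta_from_moments(m) if name == "theta" else gamma_from_moments(m)
    return out


def theta_credible_estimate(
    samples: PosteriorSamples, level: float = 0.95
) -> ThetaEstimate:
    """Equal-tailed credible interval for theta on the percent scale.

    The point estimate is the posterior mean.  Because theta's support is
    (0, 1), the nonviable fraction is structurally zero — the Bayesian
    route cannot produce intervals outside [0, 100]%.
    """
    d = 100.0 * samples.pooled("theta")
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
    return ThetaEstimate(
        method="bayes",
        point=float(d.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        se=float(d.std(ddof=1)),
        nonviable_fraction=float(np.mean((d < 0.0) | (d > 100.0))),
        draws=d,
    )
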