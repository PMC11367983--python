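"""Frequentist estimation of the neutral-balance fixation percentage.

The N balance y (kg ha^-1) is regressed on Ndfa x (%) with ordinary least
squares, y_i = beta0 + beta1 * x_i + eps_i, and the Ndfa at which the
expected balance is zero is the x-intercept theta = -beta0/beta1.  Two
classical uncertainty routes are provided:

* the delta method — a first-order Taylor expansion of the ratio, giving a
  Wald-normal confidence interval; and
* a pairs bootstrap — K row-resamples of the data, each refit by OLS, with
  a percentile interval over the K intercept ratios.

Neither route knows that theta is a percentage: intervals can spill
outside [0, 100] when data are scarce or the Ndfa range is narrow.  The
``nonviable_fraction`` diagnostic quantifies how much interval mass (delta)
or how many bootstrap draws fall outside the biologically viable range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .balances import BalanceDataset
from .errors import DomainError, ValidationError

__all__ = ["OlsFit", "ThetaEstimate", "ols_fit", "theta_point", "delta_ci", "bootstrap_ci"]

_SLOPE_EPS = 1e-12


@dataclass(frozen=True)
class OlsFit:
    """OLS estimates for the balance-vs-Ndfa line."""

    beta0: float
    beta1: float
    cov: np.ndarray  # 2x2 covariance of (beta0, beta1)
    sigma2_hat: float  # residual variance, RSS/(n-2)
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.cov.shape != (2, 2):
            raise ValidationError(f"cov must be 2x2, got shape {self.cov.shape}")
        if not np.allclose(self.cov, self.cov.T):
            raise ValidationError("cov must be symmetric")
        if self.n < 3:
            raise ValidationError(f"need n >= 3, got {self.n}")


@dataclass(frozen=True)
class ThetaEstimate:
    """A point estimate and interval for theta, on the percent scale."""

    method: str  # "delta" | "bootstrap" | "bayes"
    point: float
    ci_low: float
    ci_high: float
    level: float
    se: float | None = None
    nonviable_fraction: float | None = None
    n_degenerate: int = 0
    draws: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValidationError(f"level must be in (0, 1), got {self.level}")

    def to_dict(self) -> dict:
        """Serializable summary (the raw draws are omitted)."""
        return {
            "method": self.method,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "se": self.se,
            "nonviable_fraction": self.nonviable_fraction,
            "n_degenerate": self.n_degenerate,
        }


def ols_fit(data: BalanceDataset) -> OlsFit:
    """Least-squares fit of balance on Ndfa.

    Requires n >= 3 (so the residual variance has at least one degree of
    freedom) and a non-constant predictor.
    """
    if data.n < 3:
        raise ValidationError(f"need at least 3 observations to fit, got {data.n}")
    if np.ptp(data.x) == 0.0:
        raise ValidationError("x (Ndfa) is constant; the slope is unidentified")
    res = sm.OLS(data.y, sm.add_constant(data.x)).fit()
    return OlsFit(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        cov=np.asarray(res.cov_params()),
        sigma2_hat=float(res.mse_resid),
        n=data.n,
    )


def theta_point(fit: OlsFit) -> float:
    """theta = -beta0/beta1, the fitted x-intercept in Ndfa percent."""
    if abs(fit.beta1) < _SLOPE_EPS:
        raise DomainError(
            "slope is (numerically) zero: the balance does not respond to Ndfa, "
            "so no finite neutral point exists"
        )
    return -fit.beta0 / fit.beta1


def delta_ci(fit: OlsFit, level: float = 0.95) -> ThetaEstimate:
    """Delta-method variance and Wald confidence interval for theta.

    The gradient of -b0/b1 is g = (-1/b1, b0/b1^2); the approximate
    variance is g' Cov g and the interval is theta_hat +/- z * sqrt(var),
    assuming the ratio is asymptotically normal.  ``nonviable_fraction``
    is the mass of that normal outside [0, 100].
    """
    point = theta_point(fit)
    g = np.array([-1.0 / fit.beta1, fit.beta0 / fit.beta1**2])
    var = float(g @ fit.cov @ g)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 * (1.0 + level))
    if se > 0:
        nonviable = float(
            stats.norm.cdf(0.0, loc=point, scale=se)
            + stats.norm.sf(100.0, loc=point, scale=se)
        )
    else:
        nonviable = 0.0 if 0.0 <= point <= 100.0 else 1.0
    return ThetaEstimate(
        method="delta",
        point=point,
        ci_low=point - z * se,
        ci_high=point + z * se,
        level=level,
        se=se,
        nonviable_fraction=nonviable,
    )


def bootstrap_ci(
    data: BalanceDataset, K: int = 10_000, level: float = 0.95, seed: int = 0
) -> ThetaEstimate:
    """Pairs-bootstrap percentile interval for theta.

    Draws K row-resamples of size n with replacement, refits the line on
    each (in closed form, vectorized over resamples), and takes the
    (1-level)/2 and (1+level)/2 percentiles of the K intercept ratios.
    Resamples with a constant predictor or a numerically zero slope give
    no theta; they are excluded from the percentiles and counted in
    ``n_degenerate``.  Identical seeds give identical intervals.
    """
    if data.n < 3:
        raise ValidationError(f"need at least 3 observations, got {data.n}")
    if K < 100:
        raise ValidationError(f"need K >= 100 bootstrap resamples, got {K}")
    point = theta_point(ols_fit(data))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.n, size=(K, data.n))
    xs = data.x[idx]
    ys = data.y[idx]
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    sxx = ((xs - xm) ** 2).sum(axis=1)
    sxy = ((xs - xm) * (ys - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = sxy / sxx
        b0 = ym[:, 0] - b1 * xm[:, 0]
        theta = -b0 / b1
    valid = (sxx > 0) & (np.abs(b1) >= _SLOPE_EPS) & np.isfinite(theta)
    theta_valid = theta[valid]
    n_degenerate = int(K - theta_valid.size)
    if theta_valid.size == 0:
        raise ValidationError("every bootstrap resample was degenerate")

    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(theta_valid, [alpha, 1.0 - alpha])
    nonviable = float(np.mean((theta_valid < 0.0) | (theta_valid > 100.0)))
    return ThetaEstimate(
        method="bootstrap",
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        se=float(np.std(theta_valid, ddof=1)),
        nonviable_fraction=nonviable,
        n_degenerate=n_degenerate,
        draws=theta_valid,
    )
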