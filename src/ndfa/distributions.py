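"""Moment matching between (mean, variance) summaries and beta/gamma laws.

Informative priors in the neutral-balance regression are specified through
their first two moments — a mean and a variance elicited from independent
data — and then converted to distribution hyperparameters.  Two families
cover every parameter of the model: the beta distribution for the
neutral-balance fixation fraction theta (a proportion on (0, 1)) and the
gamma distribution for the slope and the residual standard deviation (both
positive reals).

The gamma family is parameterized as (shape, rate) throughout, never
(shape, scale): the prior mean is shape/rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InfeasibleMomentsError

__all__ = [
    "MomentPair",
    "BetaParams",
    "GammaParams",
    "beta_from_moments",
    "gamma_from_moments",
    "beta_moments",
    "gamma_moments",
]


@dataclass(frozen=True)
class MomentPair:
    """A (mean, variance) summary of a distribution."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.variance)):
            raise DomainError("moments must be finite")
        if self.variance <= 0:
            raise DomainError(f"variance must be > 0, got {self.variance}")


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters (alpha, beta) of a beta distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not (math.isfinite(v) and v > 0):
                raise DomainError(f"beta shape {name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class GammaParams:
    """Shape and *rate* of a gamma distribution (mean = shape/rate)."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        for name, v in (("shape", self.shape), ("rate", self.rate)):
            if not (math.isfinite(v) and v > 0):
                raise DomainError(f"gamma {name} must be finite and > 0, got {v}")

    @property
    def scale(self) -> float:
        """Scale parameter 1/rate, the convention numpy samplers expect."""
        return 1.0 / self.rate


def _as_moments(m: MomentPair | tuple[float, float]) -> MomentPair:
    if isinstance(m, MomentPair):
        return m
    return MomentPair(*m)


def beta_from_moments(m: MomentPair | tuple[float, float]) -> BetaParams:
    """Solve beta shape parameters matching a given mean and variance.

    With c = mean*(1-mean)/variance - 1 the solution is
    alpha = mean*c, beta = (1-mean)*c.  The pair is feasible only when
    0 < mean < 1 and variance < mean*(1-mean); otherwise an
    :class:`~ndfa.errors.InfeasibleMomentsError` is raised rather than
    clipping — silently deforming an elicited prior would be worse than
    failing loudly.
    """
    m = _as_moments(m)
    if not 0.0 < m.mean < 1.0:
        raise DomainError(f"beta mean must lie in (0, 1), got {m.mean}")
    bound = m.mean * (1.0 - m.mean)
    if m.variance >= bound:
        raise InfeasibleMomentsError(
            f"variance {m.variance} is not below mean*(1-mean) = {bound:.6g}; "
            "no beta distribution has these moments"
        )
    c = bound / m.variance - 1.0
    return BetaParams(alpha=m.mean * c, beta=(1.0 - m.mean) * c)


def gamma_from_moments(m: MomentPair | tuple[float, float]) -> GammaParams:
    """Solve gamma (shape, rate) matching a given mean and variance.

    shape = mean^2/variance, rate = mean/variance.  Any positive mean and
    variance are feasible.
    """
    m = _as_moments(m)
    if m.mean <= 0:
        raise DomainError(f"gamma mean must be > 0, got {m.mean}")
    return GammaParams(shape=m.mean**2 / m.variance, rate=m.mean / m.variance)


def beta_moments(p: BetaParams) -> MomentPair:
    """Mean alpha/(alpha+beta) and variance of a beta distribution."""
    s = p.alpha + p.beta
    return MomentPair(
        mean=p.alpha / s,
        variance=p.alpha * p.beta / (s**2 * (s + 1.0)),
    )


def gamma_moments(p: GammaParams) -> MomentPair:
    """Mean shape/rate and variance shape/rate^2 of a gamma distribution."""
    return MomentPair(mean=p.shape / p.rate, variance=p.shape / p.rate**2)
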