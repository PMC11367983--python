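"""Prior elicitation for the neutral-balance regression model.

The fraction of fixed N at which the partial balance is neutral equals the
N harvest index (NHI), so a species' prior for theta_PNB is elicited by
moment matching a beta distribution to the sample mean and variance of
independently collected NHI values.  The theta_TNB prior is derived from
the PNB moments: the mean is reduced by the fraction of whole-plant N
allocated belowground (roots plus rhizodeposition), and — because that
fraction is itself poorly known — the variance is inflated by 50% before
re-matching.

Slope and residual-scale priors default to gamma(1.6, 0.8) and
gamma(2.5, 0.05) (shape, rate): a weakly informative positive slope with
mean 2 kg ha^-1 per Ndfa %, and a residual SD with mean 50 kg ha^-1.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .balances import BalanceKind
from .distributions import (
    BetaParams,
    GammaParams,
    MomentPair,
    beta_from_moments,
    beta_moments,
)
from .errors import ValidationError

__all__ = [
    "DEFAULT_BETA1_PRIOR",
    "DEFAULT_SIGMA_PRIOR",
    "SPECIES_THETA_PRIORS",
    "ROOT_N_PROPORTION_REFERENCE",
    "PriorSet",
    "elicit_theta_pnb_prior",
    "derive_theta_tnb_prior",
    "assemble_priors",
]

DEFAULT_BETA1_PRIOR = GammaParams(shape=1.6, rate=0.8)
DEFAULT_SIGMA_PRIOR = GammaParams(shape=2.5, rate=0.05)

#: Reference informative theta priors for nine grain-legume species,
#: elicited from independent N-harvest-index literature (PNB) and the
#: belowground-allocation adjustment (TNB).  Useful as ready-made priors
#: when no species-specific NHI sample is at hand.
SPECIES_THETA_PRIORS: dict[tuple[str, BalanceKind], BetaParams] = {
    ("blue lupin", BalanceKind.PNB): BetaParams(20.26, 6.33),
    ("blue lupin", BalanceKind.TNB): BetaParams(13.94, 9.51),
    ("chickpea", BalanceKind.PNB): BetaParams(17.16, 5.76),
    ("chickpea", BalanceKind.TNB): BetaParams(8.24, 11.41),
    ("common bean", BalanceKind.PNB): BetaParams(3.30, 1.45),
    ("common bean", BalanceKind.TNB): BetaParams(1.85, 1.65),
    ("cowpea", BalanceKind.PNB): BetaParams(22.06, 14.11),
    ("cowpea", BalanceKind.TNB): BetaParams(5.82, 14.48),
    ("faba bean", BalanceKind.PNB): BetaParams(12.99, 2.53),
    ("faba bean", BalanceKind.TNB): BetaParams(10.58, 8.28),
    ("field pea", BalanceKind.PNB): BetaParams(9.04, 5.00),
    ("field pea", BalanceKind.TNB): BetaParams(4.34, 5.45),
    ("lentil", BalanceKind.PNB): BetaParams(5.35, 2.10),
    ("lentil", BalanceKind.TNB): BetaParams(2.56, 3.29),
    ("peanut", BalanceKind.PNB): BetaParams(8.47, 4.62),
    ("peanut", BalanceKind.TNB): BetaParams(5.21, 3.84),
    ("white lupin", BalanceKind.PNB): BetaParams(62.52, 14.06),
    ("white lupin", BalanceKind.TNB): BetaParams(47.94, 35.35),
}

#: Approximate fraction of whole-plant N allocated belowground per species,
#: back-calculated to two decimals as 1 - E[theta_TNB]/E[theta_PNB] from the
#: reference prior means above.  These are derived conveniences, not
#: primary measurements; prefer a literature value when available.
ROOT_N_PROPORTION_REFERENCE: dict[str, float] = {
    "blue lupin": 0.22,
    "chickpea": 0.44,
    "common bean": 0.23,
    "cowpea": 0.54,
    "faba bean": 0.33,
    "field pea": 0.31,
    "lentil": 0.39,
    "peanut": 0.12,
    "white lupin": 0.30,
}


@dataclass(frozen=True)
class PriorSet:
    """The three priors of the reparameterized balance regression."""

    theta_prior: BetaParams
    species: str = ""
    balance_kind: BalanceKind = BalanceKind.PNB
    beta1_prior: GammaParams = field(default=DEFAULT_BETA1_PRIOR)
    sigma_prior: GammaParams = field(default=DEFAULT_SIGMA_PRIOR)

    def __post_init__(self) -> None:
        object.__setattr__(self, "balance_kind", BalanceKind(self.balance_kind))
        if not isinstance(self.theta_prior, BetaParams):
            raise ValidationError("theta_prior must be a BetaParams")
        for name in ("beta1_prior", "sigma_prior"):
            if not isinstance(getattr(self, name), GammaParams):
                raise ValidationError(f"{name} must be a GammaParams")


def elicit_theta_pnb_prior(nhi_values) -> BetaParams:
    """Moment-match a beta prior to an independent NHI sample.

    The sample mean and unbiased (n-1 denominator) sample variance of the
    NHI values become the prior moments for theta_PNB.  Values must lie
    strictly inside (0, 1); a constant sample has zero variance and no
    feasible beta fit.
    """
    values = [float(v) for v in nhi_values]
    if len(values) < 2:
        raise ValidationError(f"need at least 2 NHI values, got {len(values)}")
    bad = [v for v in values if not 0.0 < v < 1.0]
    if bad:
        raise ValidationError(
            f"NHI values must lie in (0, 1); offending values: {bad[:5]}"
        )
    mean = statistics.fmean(values)
    variance = statistics.variance(values, xbar=mean)
    return beta_from_moments(MomentPair(mean=mean, variance=variance))


def derive_theta_tnb_prior(
    pnb_moments: MomentPair | BetaParams, root_n_proportion: float
) -> BetaParams:
    """Derive the theta_TNB prior from the theta_PNB moments.

    The mean shrinks by the belowground N allocation (a crop allocating
    fraction r of its N to roots needs a fraction (1-r) lower Ndfa to
    balance the same seed export once root N counts), and the variance is
    inflated by 50% to reflect the weaker evidence behind r.
    """
    if isinstance(pnb_moments, BetaParams):
        pnb_moments = beta_moments(pnb_moments)
    if not 0.0 <= root_n_proportion < 1.0:
        raise ValidationError(
            f"root_n_proportion must lie in [0, 1), got {root_n_proportion}"
        )
    tnb = MomentPair(
        mean=pnb_moments.mean * (1.0 - root_n_proportion),
        variance=1.5 * pnb_moments.variance,
    )
    return beta_from_moments(tnb)


def assemble_priors(
    theta: BetaParams,
    species: str = "",
    kind: BalanceKind | str = BalanceKind.PNB,
    beta1: GammaParams | None = None,
    sigma: GammaParams | None = None,
) -> PriorSet:
    """Bundle a theta prior with slope/scale priors into a full PriorSet.

    Slope and scale fall back to the package defaults unless overridden —
    e.g. with posterior hyperparameters from an earlier fit, the
    sequential-updating workflow.
    """
    if not isinstance(theta, BetaParams):
        raise ValidationError("theta prior is required and must be a BetaParams")
    return PriorSet(
        theta_prior=theta,
        species=species,
        balance_kind=BalanceKind(kind),
        beta1_prior=beta1 if beta1 is not None else DEFAULT_BETA1_PRIOR,
        sigma_prior=sigma if sigma is not None else DEFAULT_SIGMA_PRIOR,
    )
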