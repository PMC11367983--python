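"""Comparing the neutral-balance fixation fraction between balance kinds.

The case-study procedure asks whether accounting for belowground N lowers
the Ndfa a species needs for a neutral balance: split the collected
studies at random into two halves, fit the Bayesian model to the partial
balance on one half and the total balance on the other, subtract the two
theta posteriors draw-wise, and check whether zero falls inside the
credible interval of the difference.  Zero inside the interval means the
two fractions are not distinguishable; zero outside means they differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balances import LegumeObservation
from .bayes import PosteriorSamples
from .errors import ValidationError

__all__ = ["DifferenceSummary", "split_studies", "theta_difference"]

_DIRECTIONS = ("pnb_minus_tnb", "tnb_minus_pnb")


@dataclass(frozen=True)
class DifferenceSummary:
    """Quantile summary of the posterior difference of two thetas."""

    direction: str
    q025: float
    median: float
    q975: float
    zero_in_interval: bool
    level: float

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValidationError(f"direction must be one of {_DIRECTIONS}")
        if not self.q025 <= self.median <= self.q975:
            raise ValidationError("difference quantiles are not ordered")

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "q025": self.q025,
            "median": self.median,
            "q975": self.q975,
            "zero_in_interval": self.zero_in_interval,
            "level": self.level,
        }


def split_studies(
    observations: list[LegumeObservation], seed: int = 0
) -> tuple[list[LegumeObservation], list[LegumeObservation]]:
    """Randomly partition observations into two halves at the study level.

    Whole studies (all rows sharing a ``study_id``), not individual rows,
    are sampled without replacement into two near-equal groups, so the two
    halves are independent datasets.  Deterministic under ``seed``.
    """
    ids = sorted({o.study_id for o in observations if o.study_id is not None})
    if len(ids) < 2:
        raise ValidationError(
            f"need at least 2 distinct study_ids to split, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    half = len(perm) // 2
    group_a = set(perm[:half])
    a = [o for o in observations if o.study_id in group_a]
    b = [o for o in observations if o.study_id not in group_a]
    return a, b


def _pooled_theta(samples) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        return samples.pooled("theta")
    arr = np.asarray(samples, dtype=float).reshape(-1)
    return arr


def theta_difference(
    samples_a,
    samples_b,
    level: float = 0.95,
    direction: str = "pnb_minus_tnb",
    seed: int = 0,
) -> DifferenceSummary:
    """Posterior of the difference between two independent thetas.

    ``samples_a`` holds the PNB posterior and ``samples_b`` the TNB
    posterior (either :class:`~ndfa.bayes.PosteriorSamples` or raw draw
    arrays).  Since the two posteriors are independent, draws are paired
    by index after an independent seeded shuffle of each set, truncating
    to the shorter length.  With the default direction, positive values
    mean less fixation is needed once belowground N counts.
    """
    if direction not in _DIRECTIONS:
        raise ValidationError(f"direction must be one of {_DIRECTIONS}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    a = _pooled_theta(samples_a)
    b = _pooled_theta(samples_b)
    if a.size == 0 or b.size == 0:
        raise ValidationError("cannot difference empty posterior samples")
    rng = np.random.default_rng(seed)
    a = rng.permutation(a)
    b = rng.permutation(b)
    m = min(a.size, b.size)
    diff = a[:m] - b[:m]
    if direction == "tnb_minus_pnb":
        diff = -diff
    alpha = 0.5 * (1.0 - level)
    q_lo, med, q_hi = np.quantile(diff, [alpha, 0.5, 1.0 - alpha])
    return DifferenceSummary(
        direction=direction,
        q025=float(q_lo),
        median=float(med),
        q975=float(q_hi),
        zero_in_interval=bool(q_lo <= 0.0 <= q_hi),
        level=level,
    )
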