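"""Nitrogen-balance accounting for grain-legume trials.

A legume trial record carries the percentage of crop N derived from
atmospheric fixation (Ndfa), the aboveground N uptake, the N exported in
seed, and optionally a root factor scaling aboveground uptake to
whole-plant uptake.  From these the partial N balance (PNB, aboveground
fixed N minus seed N) and the total N balance (TNB, whole-plant fixed N
minus seed N) are computed, both in kg N per hectare.  Positive balances
mean a net soil N input; negative balances mean fixation did not
compensate the N removed with grain.

Other N inputs and outputs (fertilizer, deposition, leaching,
volatilization) are deliberately excluded: the balances here are the
simplified fixation-vs-removal budgets used to relate N balance to Ndfa.

Ndfa is carried in percent (0-100) throughout this module; it is converted
to a proportion only at the Bayesian model boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "BalanceKind",
    "LegumeObservation",
    "BalanceDataset",
    "ndfa_from_fixed",
    "root_factor",
    "total_uptake",
    "fixed_aboveground_n",
    "total_fixed_n",
    "partial_n_balance",
    "total_n_balance",
    "nhi",
    "build_dataset",
]

logger = logging.getLogger(__name__)

_PROP_TOL = 1e-9


class BalanceKind(str, Enum):
    """Which nitrogen balance a dataset carries."""

    PNB = "pnb"
    TNB = "tnb"


@dataclass(frozen=True)
class LegumeObservation:
    """One legume trial record.

    Parameters
    ----------
    species
        Crop label, e.g. ``"chickpea"``.
    ndfa_pct
        Percentage of aboveground N uptake derived from fixation, in
        [0, 100].
    aboveground_n
        Total aboveground N uptake, kg ha^-1, strictly positive.
    seed_n
        N exported with seed, kg ha^-1, non-negative.
    root_factor
        Optional multiplier >= 1 converting aboveground to whole-plant
        uptake; required for total-balance calculations.
    study_id
        Optional source-study label, used for study-level data splits.
    """

    species: str
    ndfa_pct: float
    aboveground_n: float
    seed_n: float
    root_factor: float | None = None
    study_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndfa_pct <= 100.0:
            raise ValidationError(f"ndfa_pct must be in [0, 100], got {self.ndfa_pct}")
        if not self.aboveground_n > 0:
            raise ValidationError(
                f"aboveground_n must be > 0, got {self.aboveground_n}"
            )
        if self.seed_n < 0:
            raise ValidationError(f"seed_n must be >= 0, got {self.seed_n}")
        if self.root_factor is not None and not self.root_factor >= 1.0:
            raise ValidationError(
                f"root_factor must be >= 1 when present, got {self.root_factor}"
            )


@dataclass(frozen=True)
class BalanceDataset:
    """Paired (Ndfa %, N balance) vectors ready for regression."""

    x: np.ndarray
    y: np.ndarray
    balance_kind: BalanceKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "balance_kind", BalanceKind(self.balance_kind))
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValidationError("x and y must be one-dimensional")
        if self.x.shape != self.y.shape:
            raise ValidationError(
                f"length mismatch: {self.x.size} x values vs {self.y.size} y values"
            )

    @property
    def n(self) -> int:
        return self.x.size


def ndfa_from_fixed(fixed_n: float, uptake_n: float) -> float:
    """Ndfa (%) = 100 * fixed N / N uptake."""
    if not uptake_n > 0:
        raise DomainError(f"uptake_n must be > 0, got {uptake_n}")
    if not 0.0 <= fixed_n <= uptake_n:
        raise DomainError(
            f"fixed_n must lie in [0, uptake_n], got {fixed_n} with uptake {uptake_n}"
        )
    return 100.0 * fixed_n / uptake_n


def root_factor(below_prop: float, above_prop: float) -> float:
    """Root factor = 1 + belowground/aboveground N proportion.

    ``below_prop`` and ``above_prop`` are the fractions of whole-plant N
    found below and above ground; they must sum to 1.  For a crop with 20%
    of its N belowground the factor is 1 + 0.20/0.80 = 1.25.
    """
    if not above_prop > 0:
        raise DomainError(f"above_prop must be > 0, got {above_prop}")
    if below_prop < 0:
        raise DomainError(f"below_prop must be >= 0, got {below_prop}")
    if not math.isclose(below_prop + above_prop, 1.0, abs_tol=_PROP_TOL):
        raise ValidationError(
            f"proportions must sum to 1, got {below_prop} + {above_prop}"
        )
    return 1.0 + below_prop / above_prop


def total_uptake(aboveground_n: float, root_factor: float) -> float:
    """Whole-plant N uptake: aboveground uptake times the root factor."""
    if not aboveground_n > 0:
        raise DomainError(f"aboveground_n must be > 0, got {aboveground_n}")
    if not root_factor >= 1.0:
        raise DomainError(f"root_factor must be >= 1, got {root_factor}")
    return aboveground_n * root_factor


def fixed_aboveground_n(uptake_n: float, ndfa_pct: float) -> float:
    """Aboveground fixed N: uptake * Ndfa(%) / 100."""
    if not uptake_n > 0:
        raise DomainError(f"uptake_n must be > 0, got {uptake_n}")
    if not 0.0 <= ndfa_pct <= 100.0:
        raise DomainError(f"ndfa_pct must be in [0, 100], got {ndfa_pct}")
    return uptake_n * ndfa_pct / 100.0


def total_fixed_n(uptake_n: float, root_factor: float, ndfa_pct: float) -> float:
    """Whole-plant fixed N: uptake * root factor * Ndfa(%) / 100.

    Assumes Ndfa does not differ between above- and belowground tissue,
    so the aboveground Ndfa applies to the root-scaled uptake.
    """
    if not root_factor >= 1.0:
        raise DomainError(f"root_factor must be >= 1, got {root_factor}")
    return fixed_aboveground_n(uptake_n, ndfa_pct) * root_factor


def partial_n_balance(obs: LegumeObservation) -> float:
    """PNB (kg ha^-1): aboveground fixed N minus seed N."""
    return fixed_aboveground_n(obs.aboveground_n, obs.ndfa_pct) - obs.seed_n


def total_n_balance(obs: LegumeObservation) -> float:
    """TNB (kg ha^-1): whole-plant fixed N minus seed N.

    Requires the observation's root factor; always >= the PNB of the same
    record since the factor is >= 1.
    """
    if obs.root_factor is None:
        raise ValidationError(
            f"total N balance needs a root_factor (species {obs.species})"
        )
    return (
        total_fixed_n(obs.aboveground_n, obs.root_factor, obs.ndfa_pct) - obs.seed_n
    )


def nhi(seed_n: float, aboveground_n: float) -> float:
    """N harvest index: seed N over aboveground N, in [0, 1].

    The NHI is the Ndfa proportion at which the partial balance is exactly
    neutral, which is why independent NHI samples inform the prior on the
    neutral-balance fixation fraction.  Values outside [0, 1] (possible in
    severely stressed trials) are rejected.
    """
    if not aboveground_n > 0:
        raise DomainError(f"aboveground_n must be > 0, got {aboveground_n}")
    if not 0.0 <= seed_n <= aboveground_n:
        raise ValidationError(
            f"seed_n must lie in [0, aboveground_n]; got {seed_n} vs {aboveground_n}"
        )
    return seed_n / aboveground_n


def build_dataset(
    observations: list[LegumeObservation], kind: BalanceKind | str
) -> BalanceDataset:
    """Assemble a regression dataset of (Ndfa %, balance) pairs.

    For ``kind="tnb"`` every observation must carry a root factor.  Mixing
    species is allowed (e.g. for pooled exploration) but logged, since the
    model is normally fitted per species.
    """
    kind = BalanceKind(kind)
    if not observations:
        raise ValidationError("cannot build a dataset from zero observations")
    species = {o.species for o in observations}
    if len(species) > 1:
        logger.warning(
            "building a %s dataset mixing %d species: %s",
            kind.value,
            len(species),
            ", ".join(sorted(species)),
        )
    balance = partial_n_balance if kind is BalanceKind.PNB else total_n_balance
    x = np.array([o.ndfa_pct for o in observations], dtype=float)
    y = np.array([balance(o) for o in observations], dtype=float)
    return BalanceDataset(x=x, y=y, balance_kind=kind)
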