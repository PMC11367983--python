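"""Exception types shared across the package."""


class NdfaError(ValueError):
    """Base class for all domain-specific errors."""


class DomainError(NdfaError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(NdfaError):
    """A record or dataset violates a structural invariant."""


class InfeasibleMomentsError(DomainError):
    """A (mean, variance) pair cannot be represented by the target family.

    For a beta distribution this happens when variance >= mean * (1 - mean):
    no choice of shape parameters can produce that much spread on (0, 1).
    """
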