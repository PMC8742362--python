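"""Exception hierarchy for casecausal.

Identification checks are exact statements about distributions; silent NaNs or
infinities would poison downstream ratios, so every degenerate situation has a
named error.
"""


class CaseCausalError(Exception):
    """Base class for all package errors."""


class InvalidGridError(CaseCausalError):
    """Time grid violates K >= 1 or index bounds."""


class InvalidProbabilityError(CaseCausalError):
    """A structural law returned a value outside [0, 1]."""


class NormalizationError(CaseCausalError):
    """A discrete distribution does not sum to 1."""


class EnumerationTooLargeError(CaseCausalError):
    """The trajectory state space exceeds the configured atom cap."""

    def __init__(self, atoms: int, cap: int):
        self.atoms = atoms
        self.cap = cap
        super().__init__(f"enumeration needs ~{atoms} atoms, cap is {cap}")


class UndefinedStratumError(CaseCausalError):
    """A conditioning stratum has zero probability."""


class UndefinedEstimandError(CaseCausalError):
    """An estimand is undefined (zero denominator or degenerate stratum)."""


class SamplingInfeasibleError(CaseCausalError):
    """A control draw was requested from a pool that is too small."""


class PositivityViolationError(CaseCausalError):
    """A propensity is 0 or 1 (or a stratum is missing) where a weight is needed."""


class ZeroCellError(CaseCausalError):
    """A weighted exposure cell is empty; the odds (ratio) is undefined."""
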