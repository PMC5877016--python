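"""Exception hierarchy for greycast."""


class GreyError(Exception):
    """Base class for all greycast errors."""


class InvalidSeriesError(GreyError):
    """A series violates a structural invariant (length, spacing, finiteness, sign)."""


class InsufficientDataError(GreyError):
    """Too few observations for the requested operation."""


class MissingDataError(GreyError):
    """Missing values where a complete series is required."""


class PositivityError(GreyError):
    """Non-positive base raised to a fractional power (undefined over the reals)."""


class RankDeficiencyError(GreyError):
    """The least-squares system is numerically singular.

    Carries the condition number of the design matrix in ``condition``.
    """

    def __init__(self, message: str, condition: float = float("inf")):
        super().__init__(message)
        self.condition = condition


class DegenerateModelError(GreyError):
    """A parameter value makes the model form invalid (a=0 in the time response,
    a=-2 in the derived-model transform)."""


class AlignmentError(GreyError):
    """Results or series that must share epochs do not."""


class SimulationError(GreyError):
    """The requested parameter combination produces an inadmissible series."""
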