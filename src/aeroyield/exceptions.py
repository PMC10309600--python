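"""Exception hierarchy for aeroyield.

Every error raised on bad scientific input derives from
:class:`AeroYieldError`, so callers can distinguish domain problems from
programming bugs with a single ``except``.
"""


class AeroYieldError(Exception):
    """Base class for all aeroyield domain errors."""


class ParameterDomainError(AeroYieldError, ValueError):
    """A distribution parameter is outside its mathematical domain."""


class UndefinedMomentError(AeroYieldError, ValueError):
    """A requested moment does not exist for the given tail index."""


class FeasibilityError(AeroYieldError, ValueError):
    """A moment summary lies outside the attainable region of the family."""


class InsufficientSampleError(AeroYieldError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateSampleError(AeroYieldError, ValueError):
    """Sample has zero variance where spread is required."""


class EmptyInputError(AeroYieldError, ValueError):
    """An operation received no records."""


class DegenerateLabelsError(AeroYieldError, ValueError):
    """Classification input contains only one class."""


class NonInformativeRegressionError(AeroYieldError, ValueError):
    """Effort regression slope is not positive; no crossing exists."""


class GridExceededError(AeroYieldError, ValueError):
    """Target crossing lies beyond the configured sheet grid."""

    def __init__(self, message: str, extrapolated_k: float):
        super().__init__(message)
        self.extrapolated_k = extrapolated_k


class SchemaError(AeroYieldError, ValueError):
    """Input table is missing a required column or field."""
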