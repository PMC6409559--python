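"""Exception hierarchy for vo2fit."""


class Vo2FitError(Exception):
    """Base class for all vo2fit errors."""


class InvalidInputError(Vo2FitError):
    """Malformed or non-finite input values."""


class InvalidParameterError(Vo2FitError):
    """A model parameter violates its bounds or invariants."""


class InsufficientDataError(Vo2FitError):
    """A series is too short for the requested operation."""


class EmptySeriesError(Vo2FitError):
    """An operation would leave (or received) an empty series."""


class InvalidWindowError(Vo2FitError):
    """A filter window is incompatible with the series."""


class NoOverlapError(Vo2FitError):
    """Ensemble averaging found no common time range."""


class InvalidComparisonError(Vo2FitError):
    """Model comparison requested between non-nested specifications."""


class NumericError(Vo2FitError):
    """Non-finite objective or other numerical failure during fitting."""


class UnstableFitError(Vo2FitError):
    """Too many bootstrap refits failed; carries the partial summary."""

    def __init__(self, message, partial_summary=None):
        super().__init__(message)
        self.partial_summary = partial_summary
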