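"""Exception hierarchy for the gaitbelt package.

All package-specific errors derive from :class:`GaitError` so callers can
catch one base class at pipeline boundaries.
"""


class GaitError(Exception):
    """Base class for all gaitbelt errors."""


class FormatError(GaitError):
    """A file does not have the expected columns or layout."""


class ParseError(GaitError):
    """A cell could not be parsed; the message names the offending row."""


class ValidationError(GaitError):
    """A value violates a domain invariant (range, token set, count)."""


class EmptyRecordingError(GaitError):
    """An operation that needs samples received an empty recording."""


class ParameterError(GaitError, ValueError):
    """A configuration or function parameter is out of its legal range."""


class AliasingError(ParameterError):
    """Sampling rate too low to resolve the requested signal content."""


class InsufficientStepsError(GaitError):
    """An operation that needs at least two steps received fewer."""


class DegenerateInputError(GaitError):
    """Statistically degenerate input (zero variance, constant column)."""


class SingularDesignError(DegenerateInputError):
    """Perfectly collinear regression design matrix."""


class IncompleteAssessmentError(GaitError):
    """A diagnostic component needed for classification is missing."""


class RejectionBudgetError(GaitError):
    """Rejection sampling failed to satisfy constraints within its budget."""


class UndefinedMetricError(GaitError):
    """A validation metric is undefined for the given input (empty truth)."""
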