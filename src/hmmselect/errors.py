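"""Exception hierarchy for hmmselect.

All package errors derive from :class:`HmmSelectError` so callers can catch
one base class at the pipeline boundary.
"""


class HmmSelectError(Exception):
    """Base class for all hmmselect errors."""


class DesignError(HmmSelectError):
    """Experiment design is invalid or inconsistent with the data layout."""


class ValidationError(HmmSelectError):
    """Input data failed validation (missing values, non-numeric entries)."""


class AlignmentError(HmmSelectError):
    """Objects that must share feature/condition structure do not."""


class ConfigurationError(HmmSelectError):
    """A configuration value is out of its allowed set or range."""


class ShapeError(HmmSelectError):
    """An array argument has the wrong dimensionality or size."""


class NumericalError(HmmSelectError):
    """A numerical routine failed beyond what regularization can repair."""
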