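"""Exception hierarchy for the pipeline.

All errors raised deliberately by this package derive from
:class:`OpmRamanError` so callers can catch pipeline failures without
masking programming errors.
"""


class OpmRamanError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(OpmRamanError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(OpmRamanError):
    """A calibration procedure could not produce a valid model."""


class UnderdeterminedError(CalibrationError):
    """Not enough independent observations to constrain the fit."""


class DegenerateSignalError(OpmRamanError):
    """The data carry no usable signal for the requested operation."""


class PlacementError(OpmRamanError):
    """Synthetic scene construction could not satisfy its constraints."""


class SchemaError(OpmRamanError):
    """A file is missing required datasets or metadata fields."""
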