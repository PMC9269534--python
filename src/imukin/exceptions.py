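"""Exception hierarchy shared across the package.

All data/processing failures derive from :class:`ImukinError` so the CLI can
map them to a single exit code while unit code can catch specific conditions.
"""


class ImukinError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ImukinError, ValueError):
    """An argument violates a precondition (non-finite angle, zero-norm quaternion...)."""


class EmptyInputError(ImukinError, ValueError):
    """An operation received an empty capture or series."""


class DegenerateGravityError(ImukinError, ValueError):
    """Mean acceleration too small to define the vertical axis."""


class DegenerateFieldError(ImukinError, ValueError):
    """Magnetic field (anti)parallel to gravity: static pose unusable."""


class IrregularSamplingError(ImukinError, ValueError):
    """Timestamps deviate from a uniform grid by more than the allowed jitter."""


class AlignmentError(ImukinError, ValueError):
    """Two series that must be time-aligned are not."""


class NoOverlapError(ImukinError, ValueError):
    """Two series share no common time support."""


class MalformedRowError(ImukinError, ValueError):
    """A text-dialect row has the wrong number of fields.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ParseError(ImukinError, ValueError):
    """A field could not be parsed as a number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class IncompleteRigidBodyError(ImukinError, ValueError):
    """A Motive-style export is missing one of the Yaw/Pitch/Roll columns."""


class OrderingError(ImukinError, ValueError):
    """Time column not strictly increasing."""
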