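"""Exception hierarchy for circlight.

All library errors derive from :class:`CirclightError` so callers can catch
one base class; the CLI maps them to nonzero exit codes with a diagnostic.
"""


class CirclightError(Exception):
    """Base class for all circlight errors."""


class GridError(CirclightError):
    """Two objects do not share a wavelength grid, or a grid is invalid."""


class DomainError(CirclightError):
    """A wavelength grid lies (partly) outside a function's tabulated domain."""


class SPDFormatError(CirclightError):
    """An SPD text stream violates the two-column format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class ValidationError(CirclightError):
    """An argument is outside its physical or contractual range."""


class UnscalableError(CirclightError):
    """Requested scaling of an SPD whose current target quantity is zero."""


class UndefinedPeakError(CirclightError):
    """Peak wavelength requested for an all-zero spectral function."""


class TruncationError(CirclightError):
    """A half-maximum crossing falls outside the tabulated grid."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(
            f"half-maximum crossing not bracketed on the {side}-wavelength side of the grid"
        )


class DegenerateFitError(CirclightError):
    """A fit cannot be identified from the supplied data."""


class AlignmentError(CirclightError):
    """Two dose-response curves share no overlapping response range."""


class OutOfRangeError(CirclightError):
    """A criterion response is not bracketed by a dose-response curve."""

    def __init__(self, message: str, side: str | None = None):
        self.side = side
        super().__init__(message)


class UnreachableError(CirclightError):
    """A target CS at or above the response asymptote was requested."""
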