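"""Exception hierarchy.

Every error raised by this package derives from :class:`BreastSymError` so
callers (and the CLI) can map failure categories to distinct exit codes.
"""


class BreastSymError(Exception):
    """Base class for all breastsym errors."""


class InvalidGeometryError(BreastSymError, ValueError):
    """A polygon or landmark configuration violates a geometric invariant."""


class AnnotationError(BreastSymError, ValueError):
    """An annotation violates a cross-landmark invariant (e.g. nipple outside
    its border).  ``field`` names the offending landmark."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class AnnotationFormatError(BreastSymError, ValueError):
    """An annotation or config file could not be parsed.  ``field`` names the
    missing/malformed entry when known."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class UndefinedStatisticError(BreastSymError, ArithmeticError):
    """A statistic is mathematically undefined for the given input (e.g. ICC
    with zero between-subject variance, Pearson r of a constant sequence).
    Raised explicitly rather than silently returning 0 or NaN."""
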