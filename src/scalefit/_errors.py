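"""Exception types shared across the package."""


class ScalefitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ScalefitError, ValueError):
    """A spec, config, or argument violates its invariants.

    Carries the offending field name in ``field`` when known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class FormatError(ScalefitError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class ParseError(FormatError):
    """A cell value could not be parsed; carries row/column context."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class InfeasibleRateError(ScalefitError, ValueError):
    """The requested overall missing rate cannot be reached given the
    fixed-group rate; the message states the attainable range."""


class UnimputableColumnError(ScalefitError, ValueError):
    """An item column has no observed values to impute from."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column
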