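"""Exception hierarchy shared across the package."""


class TedivError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(TedivError):
    """Malformed or inconsistent alignment input."""


class SpeciesLookupError(TedivError, KeyError):
    """A species id is not present in the alignment or annotation set."""


class CoordinateError(TedivError):
    """A position or interval falls outside the addressable sequence."""


class ParseError(TedivError):
    """A structured text file could not be parsed; carries a line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ParameterError(TedivError, ValueError):
    """An argument is outside its documented domain (e.g. T <= 0)."""


class DegenerateDataError(TedivError):
    """The requested statistic is undefined on the given data."""
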