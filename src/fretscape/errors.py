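"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError/ParseError -> 2,
DataError -> 3.
"""


class FretscapeError(Exception):
    """Base class for all package errors."""


class ValidationError(FretscapeError, ValueError):
    """An input object violates one of its documented invariants."""


class ParseError(FretscapeError, ValueError):
    """A trace/model file does not conform to its exchange format."""


class DataError(FretscapeError, ValueError):
    """Input data are insufficient or degenerate for the requested operation."""


class CorrectionStateError(FretscapeError, RuntimeError):
    """Intensity corrections applied in an invalid order (e.g. twice)."""
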