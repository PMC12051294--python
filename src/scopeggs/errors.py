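"""Exception types shared across the package."""


class ScopeggsError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(ScopeggsError):
    """A malformed record in an input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateComparisonError(ScopeggsError):
    """MMNE is undefined: the maximum and minimum entropy states coincide
    (e.g. a single-chromosome species)."""


class NoSignalError(ScopeggsError):
    """An operation that needs non-zero signal received an all-zero input."""
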