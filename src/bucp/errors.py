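"""Exception types shared across the package."""


class BucpError(Exception):
    """Base class for all package errors."""


class ValidationError(BucpError, ValueError):
    """An input value violates a documented invariant."""


class PhaseLengthError(ValidationError):
    """A phase has fewer observations than the model requires."""


class SeriesFormatError(ValidationError):
    """A series file could not be parsed into a valid series."""
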