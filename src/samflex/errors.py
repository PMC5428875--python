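"""Exception types shared across the package."""


class SamflexError(Exception):
    """Base class for all samflex errors."""


class InvalidInputError(SamflexError, ValueError):
    """A physically invalid argument (non-positive dimension, RH > 100, ...)."""


class InfeasibleShiftError(SamflexError):
    """A measured frequency shift that no physical layer modulus can produce.

    Carries the quadratic discriminant when the inversion has no real root.
    """

    def __init__(self, message: str, discriminant: float | None = None):
        super().__init__(message)
        self.discriminant = discriminant


class DegenerateInputError(SamflexError):
    """An input for which the requested quantity is mathematically indeterminate."""


class NoCrossoverError(SamflexError):
    """The modeled shift curve does not change sign on the search interval."""


class MissingBranchError(SamflexError):
    """A hydration/dehydration loop operation got a single-branch sweep."""


class ParseError(SamflexError, ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
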