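"""Exception types shared across the package."""


class OsteorateError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OsteorateError, ValueError):
    """Raised when an input object violates its documented invariants."""


class ParseError(OsteorateError, ValueError):
    """Raised when a text input (Newick, codeml output, CSV) cannot be parsed."""


class FitError(OsteorateError, RuntimeError):
    """Raised when a statistical fit cannot be performed (singular design,
    too few cases, constant variable)."""
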