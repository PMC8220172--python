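"""Exception hierarchy used across the package.

``FormatError`` signals malformed input files, ``ValidationError`` signals
inputs that parse but violate a contract, ``ParameterError`` signals bad
user-supplied parameters. All derive from ``ValueError`` so generic callers
can catch one type.
"""


class TrajlinkError(ValueError):
    """Base class for all trajlink errors."""


class FormatError(TrajlinkError):
    """A file does not conform to its declared format."""


class ValidationError(TrajlinkError):
    """Parsed input violates a semantic contract (ids, dimensions, ranges)."""


class ParameterError(TrajlinkError):
    """A user-supplied parameter is out of its valid range."""


class ComputationError(TrajlinkError):
    """A numerical procedure cannot produce a defined result."""
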