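"""Exception hierarchy shared across the pipeline.

Three broad classes map onto the CLI's exit codes: configuration errors
(bad parameters), data errors (malformed or degenerate inputs), and
numerical errors (a computation that cannot proceed on valid input).
"""


class PatchvarError(Exception):
    """Base class for all package errors."""


class ParameterError(PatchvarError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class FormatError(PatchvarError, ValueError):
    """An input file does not conform to its declared format."""


class ValidationError(PatchvarError, ValueError):
    """In-memory data violates a contract (negative counts, shape mismatch...)."""


class DegenerateGeometryError(PatchvarError, ValueError):
    """All spots share one location; no spatial scale can be defined."""


class DegenerateInputError(PatchvarError, ValueError):
    """Input admits no analysis (e.g. every feature is constant)."""


class InsufficientNullError(PatchvarError, ValueError):
    """Too few usable statistics to fit the null distribution."""


class GenerationError(PatchvarError, RuntimeError):
    """A simulation constraint could not be satisfied."""
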