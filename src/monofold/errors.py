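"""Exception taxonomy for the monofold pipeline.

All errors derive from :class:`MonofoldError` (itself a ``ValueError``) so
callers can catch pipeline failures uniformly while retaining stdlib
semantics.
"""


class MonofoldError(ValueError):
    """Base class for all monofold-specific errors."""


class FormatError(MonofoldError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class TraceParseError(MonofoldError):
    """A cell or row of a trough log could not be parsed or validated."""


class InsufficientDataError(MonofoldError):
    """Too few points to carry out an operation (segmentation, fit, ...)."""


class EquationDomainError(MonofoldError):
    """An equation of state was evaluated outside its physical domain."""
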