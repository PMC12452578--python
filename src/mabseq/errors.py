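"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are handled by click
(exit 2), :class:`ValidationError`/:class:`ParseError` map to exit 3,
:class:`QcFailure` to exit 4.
"""


class MabseqError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MabseqError):
    """An input file could not be parsed (bad character, bad field, ...)."""


class ValidationError(MabseqError):
    """An input violated a documented precondition or invariant."""


class JunctionError(MabseqError):
    """The CDR3 junction could not be resolved from V/J anchor projection."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial or {}


class ConstraintError(MabseqError):
    """No primer satisfies the requested length/Tm constraints."""


class QcFailure(MabseqError):
    """All chains failed quality control."""
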