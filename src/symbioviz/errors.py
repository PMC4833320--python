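"""Exception hierarchy.

All errors raised deliberately by this package derive from
:class:`SymbiovizError`, so callers (and the CLI) can distinguish
expected failure modes from bugs.
"""


class SymbiovizError(Exception):
    """Base class for all errors raised by symbioviz."""


class ParseError(SymbiovizError):
    """A file could not be parsed (malformed syntax)."""


class ValidationError(SymbiovizError):
    """Input parsed but violates a documented contract or invariant."""
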