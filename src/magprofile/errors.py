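"""Exception hierarchy shared across the package.

All domain errors derive from :class:`MagProfileError` so callers can catch
one base class; parsing/validation errors additionally derive from
``ValueError`` to behave naturally in generic code.
"""

from __future__ import annotations


class MagProfileError(Exception):
    """Base class for all errors raised by magprofile."""


class FormatError(MagProfileError, ValueError):
    """A table does not have the expected structure (missing column, wrong
    field count, unknown rank prefix, unknown dialect...)."""


class ParseError(FormatError):
    """A field could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MagProfileError, ValueError):
    """Parsed values violate a domain invariant (duplicate ids, negative
    counts, percentages out of range, cyclic synonym maps...)."""


class ReconciliationError(ValidationError):
    """Bin ids do not line up across input tables."""

    def __init__(self, message: str, orphans: dict[str, list[str]] | None = None):
        self.orphans = orphans or {}
        super().__init__(message)


class DegenerateInputError(MagProfileError, ValueError):
    """The computation is undefined on this input (e.g. all counts zero)."""
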