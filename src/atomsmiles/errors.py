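"""Exception hierarchy.

All package errors derive from :class:`AtomSmilesError` so callers can catch
one type; the CLI maps :class:`UsageError` to exit code 1 and every other
subclass to exit code 2.
"""

from __future__ import annotations


class AtomSmilesError(Exception):
    """Base class for all errors raised by this package."""


class UsageError(AtomSmilesError):
    """Invalid arguments or empty input where content is required."""


class SmilesParseError(AtomSmilesError):
    """A string could not be parsed as SMILES.

    ``position`` is the 0-based character offset of the first offending
    character when the failure is lexical, else ``None``.
    """

    def __init__(self, message: str, *, position: int | None = None,
                 line: int | None = None) -> None:
        self.position = position
        self.line = line
        if position is not None:
            message = f"{message} (at position {position})"
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedFeatureError(AtomSmilesError):
    """Molecule contains a feature the token scheme cannot serialize."""


class TokenFormatError(AtomSmilesError):
    """A token does not follow the expected grammar."""

    def __init__(self, message: str, *, token: str | None = None) -> None:
        self.token = token
        if token is not None:
            message = f"{message}: {token!r}"
        super().__init__(message)


class InternalConsistencyError(AtomSmilesError):
    """Projection back to SMILES produced an unparseable string."""


class DataError(AtomSmilesError):
    """A dataset-level failure; carries the offending line numbers."""

    def __init__(self, message: str, *, lines: list[int] | None = None) -> None:
        self.lines = lines or []
        if self.lines:
            message = f"{message} (lines: {', '.join(map(str, self.lines))})"
        super().__init__(message)
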