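"""Exception hierarchy.

All library errors derive from :class:`HomecageError` so callers can catch
everything with one clause; each error also derives from the matching builtin
(``ValueError``, ``KeyError``, ...) so generic handling keeps working.
"""


class HomecageError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(HomecageError, ValueError):
    """A value is outside the domain an operation is defined on."""


class FormatError(HomecageError, ValueError):
    """A file (archive member, timeline, config) violates its dialect."""


class IntegrityError(HomecageError, ValueError):
    """Cross-record references in an archive do not resolve."""


class MergeConflictError(HomecageError, ValueError):
    """Two sessions describe the same animal inconsistently."""


class RecordLookupError(HomecageError, KeyError):
    """A requested animal / group / phase name does not exist."""

    def __init__(self, message: str):
        # bypass KeyError's repr-quoting of the message
        super().__init__(message)
        self.message = message

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.message


class GenerationError(HomecageError, RuntimeError):
    """A synthetic-experiment configuration cannot be realized."""
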