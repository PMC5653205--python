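"""Typed errors shared across the package.

Every malformed input maps to one of these; nothing falls back to a
silent default.
"""


class EpoctError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpoctError):
    """A threshold registry or simulator config is missing or invalid.

    The message always names the offending field.
    """


class RecordValidationError(EpoctError):
    """A patient or follow-up record violates an eligibility invariant."""


class RangeError(EpoctError):
    """A lookup argument falls outside the bundled reference table."""


class IncompleteWorkupError(EpoctError):
    """Classification was requested before a demanded test was performed.

    The message names the missing test token.
    """


class DegenerateTableError(EpoctError):
    """A 2x2 table has a zero margin or is otherwise unusable."""


class UndefinedEstimateError(EpoctError):
    """An effect estimate is undefined (e.g., zero events in the reference arm)."""
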