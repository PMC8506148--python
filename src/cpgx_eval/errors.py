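"""Exception hierarchy for panel-evaluation errors.

All package errors derive from :class:`CpgxError` so callers can catch one
type at pipeline boundaries while tests discriminate on the subclasses.
"""


class CpgxError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CpgxError):
    """A file could not be parsed; the message names the offending line/field."""


class ValidationError(CpgxError):
    """Parsed content violates a domain invariant (bounds, references, duplicates)."""


class MissingDataError(CpgxError):
    """A required population or table entry is absent (missing is never zero)."""


class UnscorableError(CpgxError):
    """An allele lacks the activity value needed for an activity-score rule."""


class UntranslatableError(CpgxError):
    """A diplotype has no phenotype-translation entry and no scorable path."""


class RuleMismatchError(CpgxError):
    """A score rule was applied to a score-less call, or vice versa."""


class ConfigError(CpgxError):
    """A simulation or pipeline configuration value is out of range or missing."""
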