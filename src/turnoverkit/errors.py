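"""Exception hierarchy for turnoverkit.

Everything raised on bad user input derives from :class:`TurnoverKitError`
so callers can catch one type at pipeline boundaries.
"""


class TurnoverKitError(Exception):
    """Base class for all turnoverkit errors."""


class InvalidDistributionError(TurnoverKitError):
    """Mass-isotopomer intensities are unusable (all zero, or negative)."""


class DomainError(TurnoverKitError):
    """An argument lies outside its mathematical domain."""


class InsufficientDataError(TurnoverKitError):
    """Too few observations / distinct time points for the requested fit."""


class ContractError(TurnoverKitError):
    """Inconsistent inputs (e.g. mixed parent ids in a joint fit)."""


class SchemaError(TurnoverKitError):
    """A table or config does not match its declared schema."""


class IncompleteDenominatorError(TurnoverKitError):
    """Stoichiometry requested without the all-heavy (unmodified) form."""


class CalibrationError(TurnoverKitError):
    """Noise calibration could not bracket / reach the target power."""
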