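"""Exception hierarchy. All package errors derive from KinaselikeError."""


class KinaselikeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(KinaselikeError):
    """Invalid user-supplied option (unknown format, bad fraction, n <= 0...)."""


class SchemaError(KinaselikeError):
    """Malformed table, profile document or matrix (missing column,
    wrong descriptor order, unknown schema version)."""


class DegenerateProfileError(KinaselikeError):
    """A descriptor column is constant, so sd or correlation is undefined."""


class ScoringError(KinaselikeError):
    """A descriptor value is non-finite or a record is unscorable."""


class UndefinedAUCError(KinaselikeError):
    """ROC AUC requested with only one class present."""


class ContractViolationError(KinaselikeError):
    """An operation was fed input its precondition excludes
    (e.g. descriptors requested for an excluded molecule)."""
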