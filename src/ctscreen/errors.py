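"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`CTScreenError`, so callers (and the
CLI) can distinguish bad inputs from genuine bugs.
"""


class CTScreenError(Exception):
    """Base class for all errors raised by this package."""


class InputFormatError(CTScreenError):
    """A file or table violates the expected tabular format."""


class ValidationError(CTScreenError):
    """A parsed object violates a structural invariant (duplicates, NaN, ...)."""


class ReferentialIntegrityError(ValidationError):
    """Cross-table references are broken (e.g. a cancer group whose
    matched normal tissue does not exist or is not a NORMAL group)."""


class ConsistencyError(CTScreenError):
    """Two pipeline stages were run on inconsistent inputs (e.g. a contrast
    is missing probesets present in the matrix)."""


class ContractError(CTScreenError):
    """An operation was called outside its contract (e.g. the moderated
    two-sample test with a group of fewer than two samples)."""


class InsufficientDataError(CTScreenError):
    """Too little data to estimate a quantity (e.g. the variance prior)."""


class ConfigError(CTScreenError):
    """A configuration object violates its invariants."""
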