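"""Exception hierarchy shared across the package."""


class KneeGPError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(KneeGPError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(KneeGPError, ValueError):
    """An input array or argument violates a precondition."""


class TrialFormatError(KneeGPError, ValueError):
    """An on-disk trial bundle fails validation; the message names the check."""


class ConditioningError(KneeGPError, RuntimeError):
    """A kernel matrix could not be factorized even after jitter escalation."""


class StateError(KneeGPError, RuntimeError):
    """An operation was called on an object in the wrong state or mode."""


class DegenerateDataError(KneeGPError, ValueError):
    """Data is degenerate for the requested statistic (constant series,
    all-zero channel, undefined normalizer)."""
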