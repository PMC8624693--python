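"""Exception hierarchy for thermospiro.

All package-specific errors derive from :class:`ThermospiroError` so callers
can catch one base class; each also derives from ``ValueError`` because every
failure mode here is ultimately a bad input.
"""


class ThermospiroError(ValueError):
    """Base class for all thermospiro errors."""


class ConfigurationError(ThermospiroError):
    """A configuration object or call parameter violates its invariants."""


class InsufficientDataError(ThermospiroError):
    """Too few samples, frames or rows to perform the requested operation."""


class InsufficientSignalError(ThermospiroError):
    """The data carry no usable respiration signal (e.g. zero variance)."""


class ManoeuvreError(ThermospiroError):
    """A forced-manoeuvre volume trace fails a quality requirement."""


class UndefinedMetricError(ThermospiroError):
    """A metric's denominator is zero (e.g. R-squared on constant truth)."""
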