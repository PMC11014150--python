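"""Exception hierarchy for apekit.

All package errors derive from :class:`ApekitError` so callers can catch one
type at pipeline boundaries.
"""


class ApekitError(Exception):
    """Base class for all apekit errors."""


class FormatError(ApekitError):
    """A file does not conform to the declared layout (missing columns, bad dialect)."""


class DataError(ApekitError):
    """The file parsed, but its contents violate an invariant (non-monotone time,
    overlapping intervals, out-of-range values)."""


class ConfigError(ApekitError):
    """A configuration value is invalid (non-positive epoch length, unknown unit, ...)."""
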