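"""Exception hierarchy.

All package errors derive from :class:`BrainStatesError` so callers can
catch pipeline failures with a single except clause while the CLI maps
subclasses onto distinct exit codes.
"""


class BrainStatesError(Exception):
    """Base class for all errors raised by this package."""


class DataFormatError(BrainStatesError):
    """A file or table violates the expected on-disk format."""


class ValidationError(BrainStatesError):
    """An in-memory object violates a structural invariant."""


class NormalizationError(BrainStatesError):
    """Normalization is undefined for the given data (e.g. constant parcel)."""


class FitError(BrainStatesError):
    """A model fit could not be carried out on the given data."""


class StatsError(BrainStatesError):
    """A statistical test's preconditions are not met."""


class ConfigError(BrainStatesError):
    """A pipeline configuration is invalid."""
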