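"""Exception types shared across the package."""


class RepdepleteError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RepdepleteError):
    """A required column is missing from an AIRR rearrangement table."""


class EmptySampleError(RepdepleteError):
    """An input file contained no rearrangement records."""


class ValidationError(RepdepleteError):
    """A record or argument violates a documented contract."""


class LocusError(RepdepleteError):
    """An operation was applied to a sample of the wrong receptor locus."""


class ConfigError(RepdepleteError):
    """A simulation scenario configuration is infeasible or inconsistent."""


class InsufficientDataError(RepdepleteError):
    """Too few observations for the requested statistical procedure."""
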