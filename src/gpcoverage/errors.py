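"""Exception hierarchy shared across the package.

Every error raised by gpcoverage derives from :class:`GPCoverageError`, so
callers (and the CLI) can catch one base class and still report the failing
stage precisely.
"""


class GPCoverageError(Exception):
    """Base class for all gpcoverage errors."""


class SchemaError(GPCoverageError):
    """An input table is missing a required column or has an unusable dtype."""


class PanelValidationError(GPCoverageError):
    """A record violates a panel invariant; the message names (unit_id, year)."""


class DuplicateRecordError(GPCoverageError):
    """Two records share the same (unit_id, year) key."""


class CrosswalkError(GPCoverageError):
    """A unit in a covered year has no entry in the unit crosswalk."""


class BandMappingError(GPCoverageError):
    """An age-band label cannot be resolved against the configured age weights."""


class ConsistencyError(GPCoverageError):
    """Physician lists are inconsistent with unit enrolment (Σ lists > enrolled)."""


class UndefinedRatioError(GPCoverageError):
    """A ratio is requested where its denominator is zero (no FTE, no patients)."""


class DegenerateDecompositionError(GPCoverageError):
    """Decomposition endpoint has gp_fte = 0, so the list ratio is undefined."""


class UndefinedSharesError(GPCoverageError):
    """Relative shares requested for an all-zero effect vector."""


class YearGapError(GPCoverageError):
    """A yearly chain was requested over a series with missing years."""


class EmptyResultError(GPCoverageError):
    """No scope in the panel has the data required for the requested output."""


class FeasibilityError(GPCoverageError):
    """A scenario configuration cannot generate a valid panel."""


class ConfigError(GPCoverageError):
    """A pipeline or scenario configuration file is invalid."""
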