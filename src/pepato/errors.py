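"""Exception hierarchy for the pipeline.

All pipeline-specific failures derive from :class:`PepatoError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class PepatoError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PepatoError):
    """An on-disk artifact violates the expected file format."""


class ChannelMismatchError(FormatError):
    """A required EMG channel is missing from a recording."""


class InsufficientCyclesError(PepatoError):
    """Fewer gait events than needed to delimit at least one cycle."""


class InsufficientDataError(PepatoError):
    """A recording or sample set is too short for the requested analysis."""


class DegenerateCycleError(PepatoError):
    """A gait cycle spans too few raw samples to be resampled."""


class ParameterError(PepatoError, ValueError):
    """A configuration or call parameter is out of its valid range."""


class PreconditionError(PepatoError, ValueError):
    """An input violates a documented operation precondition."""


class UndefinedMetricError(PepatoError):
    """A metric (VAF, FWHM, timing, similarity) has no defined value."""


class BuildError(PepatoError):
    """A reference set cannot be built from the given subjects."""


class ConfigurationError(PepatoError):
    """Pipeline configuration inconsistent with the data or reference."""


class SchemaError(FormatError):
    """A structured file (chart, reference) violates its schema."""
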