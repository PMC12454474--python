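"""Exception hierarchy for loopscale.

All package-raised errors derive from :class:`LoopscaleError` so callers can
catch pipeline failures without masking programming errors.
"""


class LoopscaleError(Exception):
    """Base class for all loopscale errors."""


class ConfigError(LoopscaleError):
    """Invalid configuration or generative parameters."""


class InvalidSpecError(ConfigError):
    """A stroke or subject specification violates its invariants."""


class FormatError(LoopscaleError):
    """Input data violate the expected tabular/timing format."""


class TooShortError(FormatError):
    """A trajectory has too few samples for the requested filtering."""


class MissingConditionError(LoopscaleError):
    """A per-participant regression lacks one of the two condition levels."""


class CollinearityError(LoopscaleError):
    """The regression design matrix is rank deficient."""


class DegenerateSampleError(LoopscaleError):
    """A statistic is undefined on this sample (e.g. zero variance)."""


class InsufficientDataError(LoopscaleError):
    """Not enough rows/segments to compute the requested quantity."""


class PipelineError(LoopscaleError):
    """A pipeline stage failed; the stage name is attached to the message."""
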