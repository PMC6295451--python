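"""Exception hierarchy.

Every error raised by this package derives from :class:`SeizureCNNError`
so callers (and the CLI) can catch package failures in one place while
letting genuine bugs propagate.
"""


class SeizureCNNError(Exception):
    """Base class for all errors raised by seizurecnn."""


class ConfigurationError(SeizureCNNError):
    """Invalid configuration: unknown state, bad frequency, degenerate task."""


class FormatError(SeizureCNNError):
    """A file does not conform to the expected on-disk format."""


class MissingChannelError(SeizureCNNError):
    """A requested channel name is not present in the recording."""


class AnnotationError(SeizureCNNError):
    """Seizure annotations are malformed, overlapping, or out of range."""


class DataError(SeizureCNNError):
    """Signal data violate an invariant (non-finite samples, wrong shape)."""


class UndefinedMetricError(SeizureCNNError):
    """A performance metric has a zero denominator on this fold."""
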