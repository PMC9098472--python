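"""Exception types shared across the package."""


class SpikebenchError(ValueError):
    """Base class for all spikebench-specific errors."""


class ConfigurationError(SpikebenchError):
    """An invalid parameter value; the message names the offending field."""


class DataFormatError(SpikebenchError):
    """A matrix or annotation file violates the expected tabular format."""


class AnnotationError(DataFormatError):
    """Sample annotation is missing, duplicated, or inconsistent with the matrix."""
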