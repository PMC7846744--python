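"""Exception hierarchy for the range-contraction pipeline."""


class AmocRangeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AmocRangeError):
    """Invalid world/pipeline configuration."""


class GenerationError(AmocRangeError):
    """Virtual-species generation could not satisfy its constraints."""


class AlignmentError(AmocRangeError):
    """Operands live on different grids or month structures."""


class ParameterError(AmocRangeError):
    """An operation received an out-of-range or unknown parameter."""


class MetricError(AmocRangeError):
    """A validation metric is undefined for the given inputs."""


class SamplingError(AmocRangeError):
    """Background too small to draw the requested pseudoabsences."""


class FitError(AmocRangeError):
    """Model fitting failed (e.g., degenerate single-class training set)."""


class RangeUndefinedError(AmocRangeError):
    """Range change is undefined because the current range is empty."""
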