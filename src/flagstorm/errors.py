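"""Exception hierarchy shared across the pipeline stages."""


class FlagstormError(Exception):
    """Base class for all package errors."""


class ParameterError(FlagstormError, ValueError):
    """A model or configuration parameter violates an invariant."""


class RangeError(FlagstormError, ValueError):
    """An input lies outside the valid range of a calibration or band."""


class FormatError(FlagstormError, ValueError):
    """A file does not conform to the expected schema."""


class AxisFitError(FlagstormError, RuntimeError):
    """The longitudinal axis could not be determined from the point cloud."""


class AnalysisError(FlagstormError, RuntimeError):
    """An analysis stage received degenerate input."""
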