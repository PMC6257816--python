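"""Exception hierarchy shared by all pipeline stages."""


class VtaOmissionError(ValueError):
    """Base class for all domain errors raised by this package."""


class ConfigurationError(VtaOmissionError):
    """A protocol or pipeline configuration value is invalid."""


class ParameterError(VtaOmissionError):
    """A simulation parameter is out of its admissible range."""


class EpochError(VtaOmissionError):
    """A trial epoch cannot be resolved for the given session."""


class SignalError(VtaOmissionError):
    """A fluorescence signal violates an analysis precondition (e.g. F0 <= 0)."""


class WindowError(VtaOmissionError):
    """A requested analysis window is not covered by the data."""


class ResamplingError(VtaOmissionError):
    """Sampling rates are incompatible with the requested resampling."""


class StatisticsError(VtaOmissionError):
    """A statistical test received degenerate or insufficient input."""


class IntegrityError(VtaOmissionError):
    """Cross-file identifiers or manifests are inconsistent."""
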