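"""Exception types shared across the pipeline."""


class EyeFatigueError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EyeFatigueError):
    """Invalid cohort or detector configuration."""


class CalibrationError(EyeFatigueError):
    """Calibration targets are missing, malformed, or infeasible."""


class ValidationError(EyeFatigueError):
    """Invalid input data (malformed stream, response, or panel)."""


class BaselineMissingError(ValidationError):
    """A per-subject series lacks its first-epoch baseline value."""


class DegenerateDataError(EyeFatigueError):
    """Data degenerate for the requested statistic (zero range/variance)."""
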