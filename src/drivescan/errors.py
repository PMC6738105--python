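"""Exception hierarchy shared across the package."""


class DrivescanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DrivescanError):
    """A file could not be parsed; message carries the offending line number."""


class ValidationError(DrivescanError):
    """An in-memory object violates one of its invariants."""


class InsufficientDataError(DrivescanError):
    """Too few observations for the requested statistic (e.g. <3 pairs)."""


class UndefinedCorrelationError(DrivescanError):
    """Correlation undefined because a vector is constant on complete pairs."""


class ConvergenceError(DrivescanError):
    """An iterative fit did not converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class SeparationError(DrivescanError):
    """Monotone partial likelihood (perfect separation) in a Cox fit."""


class PipelineError(DrivescanError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
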