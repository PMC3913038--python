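"""Exception hierarchy shared across the package."""


class LDBridgesError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(LDBridgesError):
    """Raised when synthetic particles cannot be placed inside the field."""


class FitConvergenceError(LDBridgesError):
    """Raised when a nonlinear fit fails to converge or lands on an invalid
    optimum; carries the residuals observed at the last iterate."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class InsufficientRecoveryError(LDBridgesError):
    """Raised when a FRAP trace recovers too little to constrain D."""


class TableRangeError(LDBridgesError):
    """Raised when a ratio falls outside the tabulated correction range."""


class DegenerateVarianceError(LDBridgesError):
    """Raised when a paired comparison has zero variance in the differences."""


class ConfigError(LDBridgesError):
    """Raised for invalid pipeline configuration."""
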