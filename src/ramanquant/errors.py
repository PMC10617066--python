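"""Exception hierarchy shared across the package."""


class RamanQuantError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(RamanQuantError, ValueError):
    """Raised when a spectra CSV or a Spectrum violates the data model."""


class ConfigError(RamanQuantError, ValueError):
    """Raised when a configuration object fails validation."""


class SelectionError(RamanQuantError, ValueError):
    """Raised when a wavenumber window selects no channels."""


class SingularSystemError(RamanQuantError, ValueError):
    """Raised when the Whittaker system is singular (e.g. all-zero weights)."""


class UndefinedMetricError(RamanQuantError, ValueError):
    """Raised when a metric is requested outside its domain (constant y, R2 >= 1)."""


class TrainingDivergenceError(RamanQuantError, RuntimeError):
    """Raised when the training loss becomes non-finite.

    Attributes
    ----------
    epoch : int
        Zero-based epoch index at which the loss diverged.
    """

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training loss became non-finite at epoch {epoch}")
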