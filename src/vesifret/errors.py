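"""Exception hierarchy shared across analysis stages."""


class VesifretError(Exception):
    """Base class for all package-specific errors."""


class DomainError(VesifretError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(VesifretError, ValueError):
    """Parameters are inconsistent with each other or with the data."""


class InsufficientDataError(VesifretError, ValueError):
    """Not enough data points to perform the requested fit."""


class ConvergenceError(VesifretError, RuntimeError):
    """An iterative fit failed to converge.

    ``last_iterate`` carries the parameter vector at the final iteration
    so a caller can inspect how far the optimiser got.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateFitError(VesifretError, RuntimeError):
    """The data carry no information about the model parameters."""


class InstabilityError(VesifretError, RuntimeError):
    """Too many bootstrap replicates failed to fit."""


class RegistrationError(VesifretError, RuntimeError):
    """Channel registration failed; ``transform`` holds the identity fallback."""

    def __init__(self, message: str, transform=(0.0, 0.0)):
        super().__init__(message)
        self.transform = transform


class PackingError(VesifretError, RuntimeError):
    """Requested spot density cannot satisfy the minimum-separation constraint."""


class PipelineError(VesifretError, RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage
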