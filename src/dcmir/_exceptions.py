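"""Package-specific exception types."""


class DcmirError(Exception):
    """Base class for all package errors."""


class ParameterError(DcmirError, ValueError):
    """A user-supplied parameter violates a precondition."""


class SimulationError(DcmirError, RuntimeError):
    """Synthetic-data generation failed (instability, negative power, ...)."""


class UnstableSystemError(DcmirError, RuntimeError):
    """A dynamical system is unstable where stability is required."""
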