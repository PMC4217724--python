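"""Exception hierarchy.

Errors are split by origin: bad numeric inputs (:class:`DomainError`),
bad configuration (:class:`ConfigError`), calls made in the wrong order
(:class:`StateError`), data that cannot support an estimate
(:class:`UnderdeterminedError`, :class:`DataError`) and failures of the
nonlinear structural solver (:class:`SolverError`).
"""


class StentDegError(Exception):
    """Base class for all package errors."""


class DomainError(StentDegError, ValueError):
    """A numeric argument is outside its physical domain."""


class InvalidAnchorError(DomainError):
    """The reference-elongation anchor degradation degree is not in [0, 1)."""


class ConfigError(StentDegError, ValueError):
    """A configuration value or key is invalid."""


class StateError(StentDegError, RuntimeError):
    """An operation was requested in an invalid simulation/data state."""


class DataError(StentDegError, ValueError):
    """Observations contain non-finite or otherwise unusable values."""


class UnderdeterminedError(DataError):
    """Too few observations to identify the requested model."""


class SolverError(StentDegError, RuntimeError):
    """The nonlinear solver failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
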