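"""Exception types shared across the package."""


class TidoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TidoseError):
    """Invalid phantom / protocol / pipeline configuration."""


class UnknownElectrodeError(TidoseError, KeyError):
    """Electrode label not present in the built-in 10-10 table."""


class InfeasibleROIError(TidoseError):
    """No placement of the requested ROI satisfies the containment rule."""


class SolverError(TidoseError):
    """The discrete system is singular or otherwise unsolvable."""


class ConvergenceError(SolverError):
    """Iterative solve did not reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GridMismatchError(TidoseError):
    """Two volumes do not share the same voxel grid."""


class FormatError(TidoseError):
    """A volume file on disk could not be parsed."""
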