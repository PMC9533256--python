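"""Exception and warning types shared across the package."""


class BraincoolError(Exception):
    """Base class for all package-specific errors."""


class NoEquilibriumError(BraincoolError):
    """The perfusion-metabolism balance has no root in the physiologic bracket."""


class SolverError(BraincoolError):
    """Nonlinear iteration failed to converge.

    Carries the last fixed-point update magnitude so failed runs can be
    diagnosed from logs.
    """

    def __init__(self, message: str, residual: float | None = None):
        if residual is not None:
            message = f"{message} (last residual {residual:.3e})"
        super().__init__(message)
        self.residual = residual


class GeometryError(BraincoolError):
    """Inconsistent grids, probes outside the domain, planes outside fields."""


class AlreadyProcessedError(BraincoolError):
    """Raised when MRT postprocessing is applied to an already-processed stack."""


class MonotonicityError(BraincoolError):
    """Sweep data that should be monotone is not; usually a solver problem."""


class ConfigError(BraincoolError):
    """Invalid run configuration; message names the offending key path."""


class PhysiologyWarning(UserWarning):
    """Temperatures outside the range the perfusion/metabolism fits were built for."""
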