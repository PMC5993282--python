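"""Exception hierarchy shared across the package."""


class OdestepError(Exception):
    """Base class for all package-specific errors."""


class InputError(OdestepError, ValueError):
    """Invalid user input (shapes, non-finite values, bad options)."""


class ConfigurationError(OdestepError):
    """A capability was requested that the model/options do not provide."""


class IntegrationError(OdestepError):
    """Numerical ODE integration failed.

    Attributes
    ----------
    t_fail : float or None
        Time at which the integrator gave up, when known.
    """

    def __init__(self, message, t_fail=None):
        super().__init__(message)
        self.t_fail = t_fail


class SingularWindowError(OdestepError):
    """A local-polynomial window contained too few points for the fit."""

    def __init__(self, message, grid_point=None):
        super().__init__(message)
        self.grid_point = grid_point


class DegenerateDesignError(OdestepError):
    """Normal equations of a linear estimation step are singular."""


class UnsupportedObservationPatternError(OdestepError):
    """Missing states cannot be handled for the requested model."""


class SingularInformationError(OdestepError):
    """The Fisher information matrix is numerically singular."""

    def __init__(self, message, cond=None):
        super().__init__(message)
        self.cond = cond


class EstimationError(OdestepError):
    """Aggregate failure of an estimation pipeline (all candidates failed)."""

    def __init__(self, message, causes=None):
        super().__init__(message)
        self.causes = causes or []
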