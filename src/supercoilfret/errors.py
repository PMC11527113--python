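"""Exception hierarchy shared by all analysis and simulation stages."""


class SupercoilFretError(Exception):
    """Base class for every error raised by this package."""


class InvalidParameterError(SupercoilFretError, ValueError):
    """A numeric argument violates its contract (negative rate, gamma <= 0, ...)."""


class ContractViolationError(SupercoilFretError, ValueError):
    """An input object violates a structural precondition (schedule, trace length)."""


class ConfigurationError(SupercoilFretError, ValueError):
    """An analysis setting is inconsistent with the data it is applied to."""


class FitFailureError(SupercoilFretError, RuntimeError):
    """A nonlinear fit failed to converge or the data are degenerate.

    Carries whatever diagnostic the optimizer produced in ``details``.
    """

    def __init__(self, message: str, details=None):
        super().__init__(message)
        self.details = details


class InsufficientDataError(SupercoilFretError, ValueError):
    """Too few observations to run the requested estimator."""


class UndefinedFractionError(SupercoilFretError, ValueError):
    """A population fraction has an empty denominator."""
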