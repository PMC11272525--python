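"""Exception hierarchy shared across the package."""


class PsmCeaError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PsmCeaError, ValueError):
    """An argument violates a documented precondition."""


class NonIdentifiableError(PsmCeaError):
    """A fit was requested on data that cannot identify the parameters
    (e.g. a censored-survival likelihood with zero events)."""


class FitFailureError(PsmCeaError):
    """The optimizer did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class InsufficientDataError(PsmCeaError):
    """Too few usable observations for the requested estimator."""


class ConnectivityError(PsmCeaError):
    """The treatment network is not connected."""


class InfeasibleMomentsError(PsmCeaError):
    """Method-of-moments parameters fall outside the distribution's
    feasible region (e.g. beta with variance >= m(1-m))."""


class ConfigValidationError(PsmCeaError):
    """Configuration failed validation; message names the offending paths."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
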