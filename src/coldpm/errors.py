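"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class ColdPMError(Exception):
    """Base class for all package errors."""


class ConfigError(ColdPMError):
    """Invalid specification, configuration, or parameter value."""


class DataError(ColdPMError):
    """Input data missing, inconsistent, or insufficient for the analysis."""


class CalibrationError(ColdPMError):
    """The requested true exposure-lag surface cannot be realised."""


class ConvergenceError(ColdPMError):
    """Likelihood maximisation failed.

    Carries the last iterate and gradient norm for post-mortem inspection.
    """

    def __init__(self, message, beta=None, grad_norm=None, n_iter=None):
        super().__init__(message)
        self.beta = beta
        self.grad_norm = grad_norm
        self.n_iter = n_iter


class AliasingError(ColdPMError):
    """No (or not enough) within-stratum variation to identify coefficients."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)
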