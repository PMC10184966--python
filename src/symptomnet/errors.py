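"""Exception types shared across the package."""


class SymptomNetError(Exception):
    """Base class for all package errors."""


class ValidationError(SymptomNetError, ValueError):
    """Invalid input data (out-of-range item score, missing column, ...)."""


class ConvergenceError(SymptomNetError, RuntimeError):
    """An iterative fit failed to converge.

    Carries a ``trace`` attribute with whatever diagnostic the solver
    accumulated before giving up (sweep count, last parameter change, ...).
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
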