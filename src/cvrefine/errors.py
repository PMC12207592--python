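"""Exception hierarchy shared across the package."""


class CVRefineError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CVRefineError, ValueError):
    """Raised when inputs violate a documented precondition."""


class ConvergenceError(CVRefineError, RuntimeError):
    """Raised when an iterative solver fails to converge.

    The ``last_iterate`` attribute carries the final state so callers can
    inspect or salvage a partially converged result.
    """

    def __init__(self, message, last_iterate=None, diagnostics=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.diagnostics = diagnostics


class EmptyComponentError(CVRefineError, RuntimeError):
    """Raised when a mixture component loses all responsibility mass."""


class IntegrationError(CVRefineError, RuntimeError):
    """Raised when a dynamics integration becomes numerically unstable."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step


class NoDiscriminantError(CVRefineError, ValueError):
    """Raised when LDA cannot find a direction (zero between-class scatter)."""
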