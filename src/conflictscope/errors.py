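"""Exception types shared across the pipeline."""


class ConflictscopeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConflictscopeError):
    """Invalid configuration (non-positive grid, inconsistent sizes, ...)."""


class GenerationError(ConflictscopeError):
    """Synthetic-data generation failed (e.g. all-zero sampling intensity)."""


class ValidationError(ConflictscopeError):
    """Malformed input data (unknown category labels, NaN coordinates, ...)."""


class ConvergenceError(ConflictscopeError):
    """An iterative fit failed to converge.

    ``ridge_fallback`` records whether a ridge-penalised refit was attempted
    (complete separation in multinomial fits).
    """

    def __init__(self, message: str, ridge_fallback: bool = False):
        super().__init__(message)
        self.ridge_fallback = ridge_fallback
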