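"""Exception types shared across the package."""


class MadcError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(MadcError):
    """Inputs are inconsistently dimensioned (locations, magnitudes, responses)."""


class InvalidDataError(MadcError):
    """A table or trial log violates its schema or invariants."""


class ConvergenceError(MadcError):
    """An optimization failed to converge.

    Carries the best iterate found so far in ``best`` and free-form
    ``diagnostics`` for debugging.
    """

    def __init__(self, message, best=None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics or {}
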