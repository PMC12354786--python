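"""Exception hierarchy for wallmech.

All errors raised by the package derive from :class:`WallMechError` so
callers can catch the package's failures without masking programming
errors (TypeError, etc.).
"""


class WallMechError(Exception):
    """Base class for all wallmech errors."""


class InvalidInputError(WallMechError, ValueError):
    """Input data violates a documented precondition."""


class ConstraintInfeasibleError(WallMechError):
    """No smoothing level reaches the requested goodness of fit.

    Carries ``best_r2``, the best coefficient of determination that was
    achievable.
    """

    def __init__(self, message: str, best_r2: float):
        super().__init__(message)
        self.best_r2 = best_r2


class ExtrapolationError(WallMechError, ValueError):
    """Evaluation requested outside the fitted interval."""


class NotCyclicError(WallMechError, ValueError):
    """A cyclic operation was applied to a curve with no load reversal."""


class RangeTooShortError(WallMechError, ValueError):
    """The stretch range is too short for summary extraction."""


class PlateauNotFoundError(WallMechError):
    """The tangent-stiffness derivative never settles below the plateau
    threshold, so the final-stiffness window is undefined.

    Carries ``min_abs_dk``, the smallest |dk/dlambda| observed.
    """

    def __init__(self, message: str, min_abs_dk: float):
        super().__init__(message)
        self.min_abs_dk = min_abs_dk


class SolverError(WallMechError, RuntimeError):
    """A nonlinear solve failed to bracket or converge."""


class SchemaError(WallMechError, ValueError):
    """A CSV or config file does not match the expected schema."""
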