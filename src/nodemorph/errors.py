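"""Exception hierarchy shared across the package."""


class NodemorphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NodemorphError, ValueError):
    """A parameter violates its documented precondition."""


class DataError(NodemorphError, ValueError):
    """Input data violates a structural invariant (shape, finiteness, classes)."""


class NumericalError(NodemorphError, ArithmeticError):
    """An iterative scheme diverged or produced non-finite values."""


class EvolutionError(NodemorphError, RuntimeError):
    """Snake evolution left the image grid; carries the last valid contour."""

    def __init__(self, message, last_contour=None):
        super().__init__(message)
        self.last_contour = last_contour
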