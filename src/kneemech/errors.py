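"""Exception hierarchy shared across the package."""


class KneemechError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(KneemechError):
    """A geometric quantity violates its preconditions (e.g. L0 <= 0)."""


class InvalidParameterError(KneemechError):
    """A constitutive or configuration parameter is out of range."""


class DegenerateElementError(InvalidGeometryError):
    """An element has coincident endpoints and no line of action."""


class SolverError(KneemechError):
    """Equilibrium iteration failed to converge.

    Carries the last residual so callers can report how far off it was.
    """

    def __init__(self, message, residual=None, context=None):
        super().__init__(message)
        self.residual = residual
        self.context = context


class ModelConfigurationError(KneemechError):
    """The assembled model is ill-posed (e.g. an unrestrained DOF)."""


class ValidationError(KneemechError):
    """Input data failed validation."""
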