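"""Exception types shared across the package."""


class OlmensError(Exception):
    """Base class for package errors."""


class InvalidDesignError(OlmensError):
    """A grid design is structurally invalid (e.g. an empty value list)."""


class CalibrationError(OlmensError):
    """A calibration search could not reach its target.

    Carries the nearest achieved value so callers can report diagnostics.
    """

    def __init__(self, message: str, achieved=None):
        super().__init__(message)
        self.achieved = achieved


class DegenerateGeometryError(OlmensError):
    """Morphology geometry unusable for discretization (zero diameter etc.)."""


class InstabilityError(OlmensError):
    """Numerical divergence during integration (|V| exceeded the guard)."""

    def __init__(self, message: str, dt=None):
        super().__init__(message)
        self.dt = dt


class InvalidSiteError(OlmensError):
    """A requested recording/injection site does not exist on the morphology."""


class RegistryError(OlmensError):
    """Unknown measure name or malformed measure registry."""


class IncomparableTracesError(OlmensError):
    """No shared valid measures between two measure vectors."""


class PairingError(OlmensError):
    """Model and experimental vectors cannot be matched by protocol."""


class StageError(OlmensError):
    """A pipeline stage failed or an intermediate artifact is corrupted."""

    def __init__(self, message: str, stage=None):
        super().__init__(message)
        self.stage = stage
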