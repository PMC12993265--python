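"""Exception hierarchy for lvadhemo."""


class LvadHemoError(Exception):
    """Base class for all lvadhemo errors."""


class InvalidStepError(LvadHemoError):
    """Raised for non-positive or otherwise invalid integration steps."""


class StateError(LvadHemoError):
    """Raised when an operation is applied to an uninitialized state."""


class BackflowError(LvadHemoError):
    """Raised when a model valid only for forward pump flow sees Q <= 0."""


class NoParticlesError(LvadHemoError):
    """Raised when an aggregate is requested from an empty particle field."""


class ConvergenceError(LvadHemoError):
    """Raised when an iterative procedure fails to reach its tolerance."""


class IdentifiabilityError(LvadHemoError):
    """Raised when a dataset cannot constrain the requested parameters."""


class NoOperatingPointError(LvadHemoError):
    """Raised when the static pump curve has no real operating point."""


class InsufficientDataError(LvadHemoError):
    """Raised when fewer samples are available than an analysis requires."""


class FeasibilityError(LvadHemoError):
    """Raised when a speed-modulation spec violates the speed bounds."""


class StandardizationError(LvadHemoError):
    """Raised when per-device standardization is impossible (mean <= 0)."""


class GeneratorError(LvadHemoError):
    """Raised when synthetic-data parameters are physically inconsistent."""
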