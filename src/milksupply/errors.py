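"""Exception types and warning categories used across the package."""


class MilkSupplyError(Exception):
    """Base class for package errors."""


class InvalidInputError(MilkSupplyError, ValueError):
    """A scalar input was non-finite or otherwise unusable."""


class InsufficientEventsError(MilkSupplyError):
    """A diary has fewer than two milk-removal events, so no elapsed
    interval exists and 24 h milk production is undefined."""


class DiaryInvalidError(MilkSupplyError):
    """The diary span falls outside the accepted "24 h plus one feed"
    validity window."""


class AgeOutOfRangeError(MilkSupplyError):
    """Requested age lies outside the growth-reference grid."""


class UndefinedGainError(MilkSupplyError):
    """Average daily weight gain is undefined (infant age within the
    early neonatal regain period)."""


class DegenerateIndicatorError(MilkSupplyError):
    """An indicator column has zero variance and cannot be standardised."""


class FitFailureError(MilkSupplyError):
    """All mixture-fit restarts collapsed (an empty class or a numerical
    failure); carries per-restart diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class AmbiguousLabellingError(MilkSupplyError):
    """Fitted classes cannot be mapped unambiguously onto the canonical
    clinical labels; the message lists the class statistics."""


class UndefinedRocError(MilkSupplyError):
    """ROC analysis requested with only one outcome class present."""


class SpecError(MilkSupplyError):
    """A cohort or pipeline specification is internally inconsistent."""


class ConvergenceError(MilkSupplyError):
    """An iterative fit failed to converge; carries the gradient norm."""

    def __init__(self, message, gradient_norm=None):
        super().__init__(message)
        self.gradient_norm = gradient_norm


class DataQualityWarning(UserWarning):
    """Raised (as a warning) for recoverable data-quality issues, e.g.
    negative test-weight differences clamped to zero."""


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected in a logistic-type fit; the
    ridge-stabilised estimate is returned."""
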