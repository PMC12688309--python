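"""Exception hierarchy for climmed.

All user-facing errors derive from :class:`ClimmedError`; argument and
schema problems additionally derive from :class:`ValueError` so callers
can catch them generically.
"""


class ClimmedError(Exception):
    """Base class for all climmed errors."""


class InvalidArgumentError(ClimmedError, ValueError):
    """An argument violates a documented precondition (names the field)."""


class CalibrationError(ClimmedError, RuntimeError):
    """Intercept calibration failed (unattainable target or no bracket)."""


class SchemaError(ClimmedError, ValueError):
    """A cohort file violates the documented CSV schema."""


class EstimationError(ClimmedError, RuntimeError):
    """Base class for model-fitting failures."""


class SeparationError(EstimationError):
    """Perfect separation / degenerate response: the MLE does not exist."""

    def __init__(self, message: str, term: str | None = None):
        super().__init__(message)
        self.term = term


class RankDeficiencyError(EstimationError):
    """The design matrix is rank deficient."""


class ConvergenceError(EstimationError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class VarianceUnidentifiedError(EstimationError):
    """Random-intercept variance requested with fewer than two clusters."""


class DegenerateGroupError(ClimmedError, ValueError):
    """A comparison group is empty (descriptive statistics)."""


class BootstrapError(ClimmedError, RuntimeError):
    """Too many failed bootstrap replicates in strict mode."""


class PipelineError(ClimmedError, RuntimeError):
    """A pipeline stage failed; names the stage and carries a partial manifest."""

    def __init__(self, message: str, stage: str | None = None, manifest=None):
        super().__init__(message)
        self.stage = stage
        self.manifest = manifest
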