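"""Exception and warning types used across the package."""


class PulmorefError(Exception):
    """Base class for all package-specific errors."""


class InvalidCovariateError(PulmorefError):
    """A covariate value is outside its allowed domain (e.g. unknown PEEP level)."""


class InvalidObservationError(PulmorefError):
    """An observed value is incompatible with the outcome's transform
    (e.g. non-positive value for a log-scale outcome)."""


class SchemaError(PulmorefError):
    """A coefficient document or data table violates the expected schema."""

    def __init__(self, message, offending=None):
        super().__init__(message)
        self.offending = list(offending) if offending is not None else []


class DesignError(PulmorefError):
    """A design matrix cannot be built or is unusable (empty, rank deficient,
    under-determined)."""


class FitError(PulmorefError):
    """An estimation routine failed in a way that cannot be expressed
    through the ``converged`` flag."""


class DegenerateInputError(PulmorefError):
    """Input data is degenerate for the requested computation
    (zero variance, too few points, empty set)."""


class ApplicabilityWarning(UserWarning):
    """Covariates fall outside the mass range the reference models were
    built on; predictions are extrapolations."""
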