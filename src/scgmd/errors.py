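"""Exception types shared across the package."""


class SCGError(Exception):
    """Base class for all scgmd errors."""


class ValidationError(SCGError, ValueError):
    """Invalid parameter, moment or configuration value."""


class SingularDriftError(SCGError):
    """One-parameter nonlinearity with exponent > 1 evaluated at zero
    acceleration: the drift factor |u|^(1-eta5)/eta5 diverges.  Use the
    two-parameter family, whose drift factor is bounded."""


class UnattainableError(SCGError, ValueError):
    """Requested moment statistic lies outside the range the model family
    can produce for any parameter value."""


class InfeasibleError(SCGError, ValueError):
    """Moment-matching system has no nonnegative solution."""


class UnstableStepError(SCGError, RuntimeError):
    """Numerical integration blew up (state exceeded the overflow guard)."""
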