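"""Exception hierarchy."""


class PolyarchError(Exception):
    """Base class for all package errors."""


class ArgumentError(PolyarchError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleEffectError(PolyarchError):
    """The requested effect size cannot be realised by any relative risk
    (some genotype penetrance would exceed 1)."""


class SelectionViolationError(ArgumentError):
    """An observed statistic does not lie in its own selection region."""


class EstimationError(PolyarchError):
    """An optimiser or root-finder failed to produce an estimate."""


class EmptySelectionError(EstimationError):
    """No marker passes the requested inclusion threshold."""


class ConfigurationError(PolyarchError):
    """Inconsistent or incomplete run configuration."""
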