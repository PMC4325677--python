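"""Exception hierarchy for mvmr.

All package errors derive from :class:`MVMRError` so callers can catch one
base class; the subclasses distinguish configuration mistakes (bad column
maps, unknown axes) from data validation failures, identification problems
(too few instruments, rank deficiency) and numerical estimation failures.
"""


class MVMRError(Exception):
    """Base class for all mvmr errors."""


class ConfigurationError(MVMRError):
    """Invalid configuration: missing columns, unknown parameter names."""


class ValidationError(MVMRError):
    """Input data violate a documented invariant (e.g. non-positive SE)."""


class IdentificationError(MVMRError):
    """The causal parameters are not identified (J < K, rank deficiency)."""


class EstimationError(MVMRError):
    """Numerical estimation failed (non-convergence, singular covariance)."""
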