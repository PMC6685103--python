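"""Exception hierarchy for the dtfconn pipeline.

Every stage raises a subclass of :class:`DTFConnError` so callers can
distinguish pipeline failures from programming errors.
"""


class DTFConnError(Exception):
    """Base class for all dtfconn errors."""


class StabilityError(DTFConnError):
    """Raised when an autoregressive coefficient set is unstable.

    Carries the companion-matrix spectral radius in ``radius``.
    """

    def __init__(self, radius: float):
        self.radius = radius
        super().__init__(
            f"MVAR coefficient set is unstable: companion-matrix spectral "
            f"radius {radius:.6f} >= 1"
        )


class ConfigurationError(DTFConnError):
    """Invalid or internally inconsistent configuration."""


class ConditioningError(DTFConnError):
    """Raised when a regression design is rank-deficient or ill-conditioned."""


class SingularFrequencyError(DTFConnError):
    """A(f) is numerically singular at one or more grid frequencies."""

    def __init__(self, freqs):
        self.freqs = list(freqs)
        super().__init__(
            f"coefficient matrix A(f) singular at frequencies (Hz): {self.freqs}"
        )


class EmptyDataError(DTFConnError):
    """No data survived a filtering/rejection step."""


class InsufficientDataError(DTFConnError):
    """Too few observations for a statistical test."""


class MaskMismatchError(DTFConnError):
    """Two volumes or maps do not share the same spatial mask."""


class EmptyMaskError(DTFConnError):
    """A network mask contains no voxels (or fewer than required)."""
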