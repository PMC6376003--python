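"""Exception hierarchy for the physio-matrix pipeline.

Every stage raises a subclass of :class:`PhysioMatrixError` so that the
pipeline driver can annotate failures with the stage they came from.
"""


class PhysioMatrixError(Exception):
    """Base class for all errors raised by this package."""


class InputError(PhysioMatrixError):
    """Malformed or empty input data (CSV records, belt curves, ...)."""


class ParameterError(PhysioMatrixError):
    """Invalid analysis parameter (window length, gating mode, rates, ...)."""


class SegmentationError(PhysioMatrixError):
    """Too few physiological events to form cycles inside the span."""


class MatrixBuildError(PhysioMatrixError):
    """No valid sample could be placed in the physio-matrix."""


class EmptyBinError(PhysioMatrixError):
    """Volume integration attempted on a matrix with unfilled bins."""

    def __init__(self, empty_bins):
        self.empty_bins = list(empty_bins)
        super().__init__(
            f"physio-matrix has {len(self.empty_bins)} empty bins "
            f"(first few: {self.empty_bins[:8]}); acquire longer or use the "
            f"'gam-impute' empty-bin policy"
        )


class CoverageError(PhysioMatrixError):
    """Bin occupancy too low for the requested operation."""


class FittingError(PhysioMatrixError):
    """GAM design rank-deficient or the penalized solve failed."""


class InferenceError(PhysioMatrixError):
    """Wald test could not be computed (singular component covariance)."""


class UndefinedMetricError(PhysioMatrixError):
    """A ratio or fraction is undefined (zero denominator)."""


class CoverageWarning(UserWarning):
    """Empty-bin fraction above the configured limit."""


class SynchronizationWarning(UserWarning):
    """Shifted sample times fall outside the physiological record span."""
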