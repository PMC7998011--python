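"""Exception and warning types used across the package."""


class Band4Error(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(Band4Error, ValueError):
    """An argument violates a precondition (wrong sign, range or shape)."""


class NotAPeakError(Band4Error):
    """A profile has no half-maximum crossing on one or both sides."""


class InfeasibleDeconvolutionError(Band4Error):
    """Measured FWHM is narrower than the PSF it should be deconvolved from."""


class UnderSampledError(Band4Error):
    """Too few photon packets for a meaningful Monte Carlo histogram."""


class NoDetectedPhotonsError(Band4Error):
    """No photon packet reached the detector within the acceptance cone."""


class OutOfFieldError(Band4Error):
    """Requested eccentricity lies outside the modeled field."""


class SegmentationFailureError(Band4Error):
    """The image lacks the banded structure required for segmentation."""


class MissingBoundaryError(Band4Error, KeyError):
    """A required boundary contour is absent from a BoundarySet."""


class EmptyInputError(Band4Error):
    """All columns masked, or an empty collection was supplied."""


class WindowTooSmallError(Band4Error):
    """A fit window contains fewer samples than the model requires."""


class ConvergenceError(Band4Error):
    """Nonlinear fit failed to converge; carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class InvalidRegionError(Band4Error):
    """A requested depth region lies outside the profile."""


class FitFailureError(Band4Error):
    """Peak fitting failed (no peak, singular Jacobian, ...)."""


class DegenerateFitError(Band4Error):
    """Regression input is degenerate (e.g. all abscissae zero)."""


class UndefinedCoVError(Band4Error):
    """Coefficient of variation is undefined (zero mean)."""


class MissingCoverageError(Band4Error):
    """A sector-grid region received no thickness samples."""

    def __init__(self, message, region=None):
        super().__init__(message)
        self.region = region


class InvalidDomainError(Band4Error):
    """Function input outside the mathematical domain (e.g. log of <= 0)."""


class MissingMetadataError(Band4Error):
    """Required metadata (e.g. per-bin mean thickness) is absent."""


class UnreliableCenterWarning(UserWarning):
    """Foveal-center estimate is at the edge of the data or out of range."""
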