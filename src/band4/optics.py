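"""Axial point-spread-function arithmetic and FWHM utilities.

OCT axial resolution is set by the source coherence length.  For a
Gaussian spectrum the axial resolution in air is

    delta_z = 0.44 * lambda_0**2 / d_lambda

with ``lambda_0`` the central wavelength and ``d_lambda`` the FWHM
bandwidth.  The coherence envelope is a *field* quantity; OCT images
display intensity (the squared envelope), whose Gaussian FWHM is the
field FWHM divided by sqrt(2).  Because a measured Gaussian band is the
convolution of the true (Gaussian) axial reflectance profile with the
Gaussian intensity PSF, widths add in quadrature and the true width is
recovered by quadrature subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleDeconvolutionError, InvalidInputError, NotAPeakError
from .profile import DepthProfile

__all__ = [
    "GAUSSIAN_FWHM_PER_SIGMA",
    "AxialPSF",
    "axial_resolution_air",
    "field_to_intensity_fwhm",
    "gaussian_fwhm_from_sigma",
    "sigma_from_gaussian_fwhm",
    "fwhm_of_profile",
    "deconvolve_fwhm",
]

#: 2 * sqrt(2 ln 2) — FWHM of a unit-sigma Gaussian.
GAUSSIAN_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def axial_resolution_air(center_wavelength_nm: float, bandwidth_fwhm_nm: float) -> float:
    """Axial (field) resolution in air, in µm.

    Parameters are the central wavelength and FWHM bandwidth in nm.
    """
    if center_wavelength_nm <= 0 or bandwidth_fwhm_nm <= 0:
        raise InvalidInputError("wavelength and bandwidth must be positive")
    return 0.44 * center_wavelength_nm**2 / bandwidth_fwhm_nm / 1000.0


def field_to_intensity_fwhm(field_fwhm_um: float) -> float:
    """FWHM of the squared (intensity) Gaussian envelope: field / sqrt(2)."""
    if field_fwhm_um < 0:
        raise InvalidInputError("FWHM must be non-negative")
    return field_fwhm_um / math.sqrt(2.0)


def gaussian_fwhm_from_sigma(sigma_um: float) -> float:
    """FWHM of a Gaussian with standard deviation ``sigma_um``."""
    if sigma_um < 0:
        raise InvalidInputError("sigma must be non-negative")
    return GAUSSIAN_FWHM_PER_SIGMA * sigma_um


def sigma_from_gaussian_fwhm(fwhm_um: float) -> float:
    """Inverse of :func:`gaussian_fwhm_from_sigma`."""
    if fwhm_um < 0:
        raise InvalidInputError("FWHM must be non-negative")
    return fwhm_um / GAUSSIAN_FWHM_PER_SIGMA


@dataclass(frozen=True)
class AxialPSF:
    """Gaussian axial point-spread function of the OCT system.

    ``field_fwhm`` is the coherence-envelope FWHM (µm); the intensity
    FWHM is derived from it.  ``grid_spacing`` is the axial sampling the
    PSF will be evaluated on and must satisfy Nyquist for the intensity
    PSF (spacing <= intensity FWHM / 2).
    """

    field_fwhm: float
    grid_spacing: float = 0.05

    def __post_init__(self) -> None:
        if self.field_fwhm <= 0:
            raise InvalidInputError("field_fwhm must be positive")
        if self.grid_spacing <= 0:
            raise InvalidInputError("grid_spacing must be positive")
        if self.grid_spacing > self.intensity_fwhm / 2.0 + 1e-12:
            raise InvalidInputError(
                "grid_spacing must be <= intensity FWHM / 2 (Nyquist for the PSF)"
            )

    @property
    def intensity_fwhm(self) -> float:
        return field_to_intensity_fwhm(self.field_fwhm)

    @property
    def intensity_sigma(self) -> float:
        return sigma_from_gaussian_fwhm(self.intensity_fwhm)

    @classmethod
    def from_wavelengths(
        cls,
        center_wavelength_nm: float,
        bandwidth_fwhm_nm: float,
        grid_spacing: float = 0.05,
        medium_index: float = 1.0,
    ) -> "AxialPSF":
        """Build from source spectrum; ``medium_index`` divides the
        in-air resolution to give the in-tissue field FWHM.  The index is
        a free parameter: the package does not hard-code a tissue index.
        """
        if medium_index <= 0:
            raise InvalidInputError("medium_index must be positive")
        field = axial_resolution_air(center_wavelength_nm, bandwidth_fwhm_nm) / medium_index
        return cls(field_fwhm=field, grid_spacing=grid_spacing)


def _cross_half(z: np.ndarray, y: np.ndarray, half: float, side: str, i_peak: int) -> float:
    """Interpolated half-maximum crossing left or right of the peak."""
    if side == "left":
        idx = np.nonzero(y[: i_peak + 1] <= half)[0]
        if idx.size == 0:
            raise NotAPeakError("no half-maximum crossing left of the peak")
        i = idx[-1]
        z0, z1, y0, y1 = z[i], z[i + 1], y[i], y[i + 1]
    else:
        idx = np.nonzero(y[i_peak:] <= half)[0]
        if idx.size == 0:
            raise NotAPeakError("no half-maximum crossing right of the peak")
        i = i_peak + idx[0]
        z0, z1, y0, y1 = z[i - 1], z[i], y[i - 1], y[i]
    if y1 == y0:
        return z1
    return z0 + (half - y0) * (z1 - z0) / (y1 - y0)


def fwhm_of_profile(profile: DepthProfile) -> float:
    """FWHM of a single-peaked profile by linear interpolation.

    The profile must have a unique global maximum strictly above both of
    its boundary values; the two half-maximum crossings nearest the peak
    are located by linear interpolation between grid samples.
    """
    y = profile.intensity
    z = profile.z
    i_peak = int(np.argmax(y))
    peak = y[i_peak]
    if peak <= y[0] or peak <= y[-1]:
        raise NotAPeakError("profile maximum does not exceed its boundary values")
    half = peak / 2.0
    left = _cross_half(z, y, half, "left", i_peak)
    right = _cross_half(z, y, half, "right", i_peak)
    return float(right - left)


def deconvolve_fwhm(
    measured_fwhm: float,
    psf_intensity_fwhm: float,
    true_profile: str = "gaussian",
) -> float:
    """Remove the PSF contribution from a measured FWHM.

    With ``true_profile="gaussian"`` (default) the true and PSF widths
    add in quadrature and sqrt(measured^2 - psf^2) is returned; the
    measured 2.50 µm Bruch's membrane width against a 0.71 µm intensity
    PSF corrects to 2.40 µm.  With ``true_profile="rectangular"`` the
    FWHM of the convolved profile already equals the true width and the
    input is returned unchanged.
    """
    if psf_intensity_fwhm < 0:
        raise InvalidInputError("psf_intensity_fwhm must be non-negative")
    if true_profile == "rectangular":
        if measured_fwhm < 0:
            raise InvalidInputError("measured_fwhm must be non-negative")
        return float(measured_fwhm)
    if true_profile != "gaussian":
        raise InvalidInputError(f"unknown true_profile mode: {true_profile!r}")
    if measured_fwhm < psf_intensity_fwhm:
        raise InfeasibleDeconvolutionError(
            f"measured FWHM {measured_fwhm} < PSF FWHM {psf_intensity_fwhm}"
        )
    return float(math.sqrt(measured_fwhm**2 - psf_intensity_fwhm**2))
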