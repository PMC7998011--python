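"""Shared fixtures: one rendered synthetic eye, reused across test modules."""

import numpy as np
import pytest

from band4.optics import AxialPSF
from band4.phantom import ScanProtocol, default_phantom, render_radial_set


@pytest.fixture(scope="session")
def psf():
    return AxialPSF(field_fwhm=1.0, grid_spacing=0.05)


@pytest.fixture(scope="session")
def protocol():
    return ScanProtocol()


@pytest.fixture(scope="session")
def clean_eye(psf, protocol):
    """Noise-free default eye: (RadialScanSet, GroundTruth)."""
    return render_radial_set(default_phantom(), protocol, seed=11, psf=psf, speckle=False)


@pytest.fixture(scope="session")
def speckled_eye(psf, protocol):
    """Speckled default eye (30-frame averaging): (RadialScanSet, GroundTruth)."""
    return render_radial_set(default_phantom(), protocol, seed=11, psf=psf, speckle=True)
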