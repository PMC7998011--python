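"""Synthetic-retina generator: calibration, rendering and noise statistics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from band4.errors import OutOfFieldError
from band4.optics import AxialPSF, fwhm_of_profile
from band4.phantom import (
    BOUNDARY_ORDER,
    CohortSpec,
    ScanProtocol,
    base_rpe_thickness,
    default_cohort_spec,
    default_phantom,
    draw_cohort,
    render_ascan,
    render_radial_set,
)
from band4.profile import DepthProfile


def ring_mean(lo, hi):
    num = integrate.quad(lambda r: base_rpe_thickness(r) * r, lo, hi)[0]
    return num / ((hi**2 - lo**2) / 2)


def test_true_profile_hits_printed_sector_means():
    """Area-weighted means over the standard circles: 11.13 / 10.55 / 9.56 um."""
    assert base_rpe_thickness(0.0) == pytest.approx(11.13, abs=1e-6)
    assert ring_mean(0.0, 0.375) == pytest.approx(11.13, abs=1e-3)
    assert ring_mean(0.375, 1.125) == pytest.approx(10.55, abs=1e-3)
    assert ring_mean(1.125, 2.25) == pytest.approx(9.56, abs=1e-3)


def test_sector_ratio_matches_proportional_slope_range():
    ratio = ring_mean(1.125, 2.25) / ring_mean(0.0, 0.375)
    assert 0.85 <= ratio <= 0.86


def test_profile_non_increasing():
    r = np.linspace(0, 3.0, 400)
    t = base_rpe_thickness(r)
    assert np.all(np.diff(t) <= 1e-9)


def test_cohort_draw_unit_mean_and_spread():
    spec = default_cohort_spec(n_eyes=200, seed=1)
    eyes = draw_cohort(spec)
    scales = np.array([e.eye_scale_factor for e in eyes])
    bms = np.array([e.bm_true_fwhm for e in eyes])
    assert scales.mean() == pytest.approx(1.0, abs=1e-12)
    assert bms.mean() == pytest.approx(2.40, abs=1e-9)
    assert scales.std() == pytest.approx(spec.between_eye_sd, rel=0.25)


def test_isolated_bm_band_has_quadrature_width(psf, protocol):
    """Only the BM band rendered, no noise: FWHM = sqrt(true^2 + psf^2)."""
    eye = default_phantom()
    eye = replace(
        eye,
        tail_amplitude=0.0,
        chorio_amplitude=0.0,
        band_reflectivities={k: (0.9 if k == "BM" else 0.0) for k in eye.band_reflectivities},
    )
    scan, gt = render_radial_set(eye, protocol, seed=1, psf=psf, speckle=False)
    col = scan.images[0][:, 420]
    z = np.arange(col.size) * protocol.axial_pixel
    sel = np.abs(z - gt.contours_px["BM_peak"][0, 420] * protocol.axial_pixel) < 8
    measured = fwhm_of_profile(DepthProfile(z[sel], col[sel]))
    assert measured == pytest.approx(np.hypot(2.40, psf.intensity_fwhm), rel=0.02)


def test_speckle_variance_scales_with_frames(psf):
    """Averaged fully developed speckle: var proportional to 1/n_frames."""
    eye = default_phantom()
    variances = {}
    for frames in (5, 20):
        proto = ScanProtocol(frames_for_averaging=frames)
        vals = []
        for seed in range(50):
            prof = render_ascan(eye, 1.0, psf, proto, seed=seed)
            vals.append(prof.intensity[650])  # a bright band row
        variances[frames] = np.var(vals, ddof=1)
    ratio = variances[5] / variances[20]
    assert ratio == pytest.approx(4.0, rel=0.45)


def test_rpe_interior_darkens_with_depth(clean_eye, protocol):
    """Intensity at the basal RPE is below the apical value at every eccentricity."""
    scan, gt = clean_eye
    img = scan.images[0]
    for c in range(0, img.shape[1], 97):
        top = gt.contours_px["RPE_apical"][0, c]
        bot = gt.contours_px["BM_inner"][0, c]
        apical = img[int(round(top)) + 2, c]
        basal = img[int(round(bot)) - 2, c]
        assert basal < apical


def test_boundaries_never_invert(clean_eye):
    _, gt = clean_eye
    arr = np.stack([gt.contours_px[n] for n in BOUNDARY_ORDER])
    assert np.all(np.diff(arr, axis=0) > 0)


def test_seeded_determinism(psf, protocol):
    a, _ = render_radial_set(default_phantom(), protocol, seed=3, psf=psf)
    b, _ = render_radial_set(default_phantom(), protocol, seed=3, psf=psf)
    np.testing.assert_array_equal(a.images, b.images)


def test_ground_truth_thickness_matches_profile(clean_eye):
    _, gt = clean_eye
    eye = default_phantom()
    np.testing.assert_allclose(
        gt.rpe_thickness_um, eye.rpe_thickness(gt.eccentricity_mm), rtol=1e-12
    )


def test_centered_phantom_minimum_at_center(clean_eye, protocol):
    """With zero centration error the foveal pit minimum sits at the central column."""
    _, gt = clean_eye
    eye = default_phantom()
    inner = eye.inner_retina_thickness(gt.eccentricity_mm[0])
    assert abs(int(np.argmin(inner)) - (protocol.ascans_per_line - 1) // 2) <= 1


def test_centration_error_shifts_the_minimum(psf):
    proto = ScanProtocol(ascans_per_line=300)
    eye = replace(default_phantom(), centration_error=(0.3, 0.0))
    _, gt = render_radial_set(eye, proto, seed=1, psf=psf, speckle=False)
    inner = default_phantom().inner_retina_thickness(gt.eccentricity_mm[0])
    ds = proto.column_positions_mm[1] - proto.column_positions_mm[0]
    expected_shift = -0.3 / ds
    actual = int(np.argmin(inner)) - (proto.ascans_per_line - 1) // 2
    assert actual == pytest.approx(expected_shift, abs=1.5)


def test_out_of_field_eccentricity_rejected(psf, protocol):
    with pytest.raises(OutOfFieldError):
        render_ascan(default_phantom(), 99.0, psf, protocol, seed=0)


def test_tiff_round_trip(tmp_path, psf):
    proto = ScanProtocol(ascans_per_line=64)
    scan, _ = render_radial_set(default_phantom(), proto, seed=2, psf=psf)
    path = tmp_path / "scan.tiff"
    scan.to_tiff(path)
    back = type(scan).from_tiff(path)
    np.testing.assert_allclose(back.images, scan.images.astype(np.float32), rtol=1e-6)
    assert back.protocol.ascans_per_line == 64
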