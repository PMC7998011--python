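"""Depth-resolved RPE interior intensity by eccentricity."""

from dataclasses import replace

import numpy as np
import pytest

from band4.errors import InvalidDomainError, MissingMetadataError
from band4.phantom import ScanProtocol, default_phantom, render_radial_set
from band4.rpe_profile import (
    RPEIntensityProfile,
    combine_profiles,
    internal_intensity_profile,
    log_decay_rate,
    to_absolute_depth,
)
from band4.segmentation import BoundarySet, segment_boundaries


def flat_rpe_case(value=2.0, n_cols=400, n_rows=120):
    """Uniform-intensity 'RPE' slab with fabricated contours."""
    img = np.full((n_rows, n_cols), value)
    bs = BoundarySet(
        contours={
            "RPE_apical": np.full(n_cols, 30.0),
            "BM_inner": np.full(n_cols, 70.0),
        },
        axial_pixel_um=0.35,
        image_shape=(n_rows, n_cols),
    )
    ecc = np.linspace(-2.2, 2.2, n_cols)
    return img, bs, ecc


def test_uniform_rpe_gives_flat_unit_profile():
    img, bs, ecc = flat_rpe_case()
    prof = internal_intensity_profile(img, bs, ecc)
    ok = prof.bin_ok()
    np.testing.assert_allclose(prof.normalized_intensity[ok], 1.0, rtol=1e-9)


def test_zero_percent_depth_value_is_one(clean_eye, protocol):
    scan, gt = clean_eye
    bs = segment_boundaries(scan.images[0], protocol.axial_pixel)
    prof = internal_intensity_profile(scan.images[0], bs, gt.eccentricity_mm[0])
    ok = prof.bin_ok()
    np.testing.assert_allclose(prof.normalized_intensity[ok, 0], 1.0, rtol=1e-9)


def test_normalization_idempotent(clean_eye, protocol):
    scan, gt = clean_eye
    bs = segment_boundaries(scan.images[0], protocol.axial_pixel)
    prof = internal_intensity_profile(scan.images[0], bs, gt.eccentricity_mm[0])
    renorm = prof.normalized_intensity / prof.normalized_intensity[:, [0]]
    np.testing.assert_allclose(renorm, prof.normalized_intensity, rtol=1e-12)


def test_profile_invariant_to_image_scaling(clean_eye, protocol):
    scan, gt = clean_eye
    bs = segment_boundaries(scan.images[0], protocol.axial_pixel)
    a = internal_intensity_profile(scan.images[0], bs, gt.eccentricity_mm[0])
    b = internal_intensity_profile(scan.images[0] * 55.0, bs, gt.eccentricity_mm[0])
    np.testing.assert_allclose(a.normalized_intensity, b.normalized_intensity, rtol=1e-9)


def test_larger_drop_at_smaller_eccentricity(clean_eye, protocol):
    """The intensity at 100% RPE depth is lower centrally than peripherally."""
    scan, gt = clean_eye
    bs = segment_boundaries(scan.images[0], protocol.axial_pixel)
    prof = internal_intensity_profile(scan.images[0], bs, gt.eccentricity_mm[0])
    ok = np.nonzero(prof.bin_ok())[0]
    inner_drop = prof.normalized_intensity[ok[0], -1]
    outer_drop = prof.normalized_intensity[ok[-1], -1]
    assert inner_drop < outer_drop


def test_small_bins_excluded():
    img, bs, ecc = flat_rpe_case(n_cols=400)
    prof = internal_intensity_profile(img, bs, ecc, min_columns=50)
    # the widest bins survive, narrow ones are flagged out
    assert (~prof.bin_ok()).any()
    assert prof.bin_ok().any()


def test_absolute_depth_conversion():
    pct = np.arange(0.0, 101.0, 2.0)
    prof = RPEIntensityProfile(
        pct_depth_grid=pct,
        normalized_intensity=np.exp(-0.04 * pct)[None, :],
        eccentricity_bins=((0.0, 0.5),),
        mean_rpe_thickness=np.array([10.0]),
        n_columns=np.array([100]),
    )
    curves = to_absolute_depth(prof)
    z, y = curves[(0.0, 0.5)]
    assert z[-1] == pytest.approx(10.0, abs=0.26)
    # 50% depth maps to 5 um
    assert np.interp(5.0, z, y) == pytest.approx(np.exp(-0.04 * 50.0), rel=1e-3)


def test_absolute_depth_requires_thickness():
    pct = np.arange(0.0, 101.0, 2.0)
    prof = RPEIntensityProfile(
        pct_depth_grid=pct,
        normalized_intensity=np.ones((1, pct.size)),
        eccentricity_bins=((0.0, 0.5),),
        mean_rpe_thickness=np.array([np.nan]),
        n_columns=np.array([100]),
    )
    with pytest.raises(MissingMetadataError):
        to_absolute_depth(prof)


def test_log_decay_rate_exact_exponential():
    z = np.arange(0.0, 10.0, 0.1)
    assert log_decay_rate(z, np.exp(-0.4 * z), (1.0, 6.0)) == pytest.approx(0.4, abs=1e-9)


def test_log_decay_rate_constant_is_zero():
    z = np.arange(0.0, 10.0, 0.1)
    assert log_decay_rate(z, np.ones_like(z), (1.0, 6.0)) == pytest.approx(0.0, abs=1e-12)


def test_log_decay_rate_rejects_nonpositive():
    z = np.arange(0.0, 10.0, 0.1)
    with pytest.raises(InvalidDomainError):
        log_decay_rate(z, 1.0 - 0.2 * z, (0.0, 10.0))


def test_attenuation_rate_recovery_on_tail_free_phantom(psf):
    """With the scattering tail off, the measured log-decay rate is ~2x the
    generator's one-way attenuation coefficient (round-trip light path)."""
    proto = ScanProtocol(ascans_per_line=300)
    eye = replace(default_phantom(), tail_amplitude=0.0)
    scan, gt = render_radial_set(eye, proto, seed=4, psf=psf, speckle=False)
    bs = segment_boundaries(scan.images[0], proto.axial_pixel)
    prof = internal_intensity_profile(scan.images[0], bs, gt.eccentricity_mm[0], min_columns=20)
    rates = []
    for bin_, (z, y) in to_absolute_depth(prof).items():
        if z[-1] < 4.0:
            continue
        rates.append(log_decay_rate(z, y, (2.0, 3.5)))
    rates = np.array(rates)
    assert np.all(np.abs(rates - 2 * eye.rpe_attenuation) < 0.15 * 2 * eye.rpe_attenuation)


def test_rates_similar_across_bins_on_default_phantom(clean_eye, protocol):
    """Absolute-depth log decay rates over 2-3 um agree across bins within 15%."""
    scan, gt = clean_eye
    bs = segment_boundaries(scan.images[0], protocol.axial_pixel)
    prof = internal_intensity_profile(scan.images[0], bs, gt.eccentricity_mm[0])
    rates = []
    for bin_, (z, y) in to_absolute_depth(prof).items():
        if z[-1] < 3.5:
            continue
        rates.append(log_decay_rate(z, y, (2.0, 3.0)))
    rates = np.array(rates)
    assert rates.size >= 3
    assert (rates.max() - rates.min()) / rates.mean() < 0.15


def test_combine_profiles_preserves_normalization(clean_eye, protocol):
    scan, gt = clean_eye
    profs = []
    for a in range(2):
        bs = segment_boundaries(scan.images[a], protocol.axial_pixel)
        profs.append(internal_intensity_profile(scan.images[a], bs, gt.eccentricity_mm[a]))
    combined = combine_profiles(profs)
    ok = combined.bin_ok()
    np.testing.assert_allclose(combined.normalized_intensity[ok, 0], 1.0, rtol=1e-9)
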