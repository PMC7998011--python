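"""Tail fitting, tail subtraction and Gaussian BM quantification."""

import numpy as np
import pytest

from band4.bmquant import (
    BMQuantConfig,
    TailFit,
    average_and_normalize,
    coefficient_of_variation,
    fit_bm_gaussian,
    fit_tail,
    quantify_profile,
    subtract_tail,
)
from band4.errors import EmptyInputError, InvalidInputError, UndefinedCoVError, WindowTooSmallError
from band4.optics import GAUSSIAN_FWHM_PER_SIGMA, sigma_from_gaussian_fwhm
from band4.profile import DepthProfile


def make_profile(tail_amp=0.0, tail_k=0.1, noise=0.0, seed=0, bm_fwhm=2.40, psf_fwhm=0.707):
    """Synthetic averaged A-scan: Gaussian BM at z=0 plus an optional tail."""
    z = np.arange(-12.0, 6.0, 0.35)
    sigma = np.hypot(
        sigma_from_gaussian_fwhm(bm_fwhm), sigma_from_gaussian_fwhm(psf_fwhm)
    )
    y = np.exp(-(z**2) / (2 * sigma**2))
    y += tail_amp * np.exp(-tail_k * (z + 12.0))
    if noise:
        y += np.random.default_rng(seed).normal(0, noise, z.size)
    y = np.clip(y, 0, None)
    return DepthProfile(z, y / y.max()), sigma


def test_average_and_normalize_peak_is_one():
    stack = np.tile(np.array([1.0, 3.0, 2.0])[:, None], (1, 7))
    prof = average_and_normalize(stack)
    assert prof.intensity.max() == 1.0
    np.testing.assert_allclose(prof.intensity, [1 / 3, 1.0, 2 / 3])


def test_average_and_normalize_identical_columns_returns_column():
    col = np.array([0.5, 2.0, 1.0, 0.2])
    stack = np.tile(col[:, None], (1, 5))
    prof = average_and_normalize(stack)
    np.testing.assert_allclose(prof.intensity, col / col.max())


def test_average_rejects_all_masked():
    with pytest.raises(EmptyInputError):
        average_and_normalize(np.ones((4, 3)), mask=np.array([True, True, True]))


def test_averaging_reduces_speckle_as_sqrt_n():
    rng = np.random.default_rng(1)
    z = np.arange(50.0)
    base = np.full(50, 2.0)
    sds = []
    for n_cols in (8, 32):
        reps = []
        for _ in range(50):
            stack = rng.exponential(base[:, None], size=(50, n_cols))
            reps.append(average_and_normalize(stack, z=z).intensity[10])
        sds.append(np.std(reps, ddof=1))
    assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.4)


def test_cubic_fit_recovers_exact_polynomial():
    z = np.arange(-10.0, -2.0, 0.2)
    coef = np.array([0.4, -0.05, 0.003, 0.0002])
    y = coef[0] + coef[1] * z + coef[2] * z**2 + coef[3] * z**3
    prof = DepthProfile(z, np.clip(y, 0, None))
    fit = fit_tail(prof, (-10, -2.2), model="cubic")
    np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-6)
    assert fit.residual_rms < 1e-10


def test_biexp_fit_nests_single_exponential():
    z = np.arange(-10.0, -2.0, 0.2)
    y = 0.8 * np.exp(-0.3 * (z + 12))
    fit = fit_tail(DepthProfile(z, y), (-10, -2.2), model="biexp")
    assert fit.residual_rms < 1e-6 * y.max()
    np.testing.assert_allclose(fit.predict(z), y, rtol=1e-4)


def test_tail_fit_on_pure_noise_reports_noise_level():
    rng = np.random.default_rng(4)
    z = np.arange(-10.0, -2.0, 0.1)
    y = 1.0 + rng.normal(0, 0.05, z.size)
    fit = fit_tail(DepthProfile(z, np.clip(y, 0, None)), (-10, -2.1), model="cubic")
    assert fit.residual_rms == pytest.approx(0.05, rel=0.35)


def test_window_too_small():
    z = np.arange(-10.0, -2.0, 0.2)
    with pytest.raises(WindowTooSmallError):
        fit_tail(DepthProfile(z, np.ones_like(z)), (-3.0, -2.2), model="cubic")


def test_zero_tail_subtraction_is_identity():
    prof, _ = make_profile()
    tail = TailFit("cubic", np.zeros(4), (-10, -3), (-3, 3), 0.0)
    out, clipped = subtract_tail(prof, tail, (-3, 3))
    np.testing.assert_array_equal(out.intensity, prof.intensity)
    assert clipped == 0.0


def test_gaussian_fit_exact_recovery():
    z = np.arange(-5.0, 5.0, 0.1)
    sigma, amp, base = 1.06, 0.9, 0.05
    y = amp * np.exp(-(z**2) / (2 * sigma**2)) + base
    params, r2 = fit_bm_gaussian(DepthProfile(z, y), (-4, 4))
    assert params[0] == pytest.approx(amp, rel=1e-6)
    assert params[2] == pytest.approx(sigma, rel=1e-6)
    assert params[3] == pytest.approx(base, abs=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_uncorrected_tail_biases_width_high():
    """A residual tail inflates the FWHM and lowers R^2 versus tail correction."""
    prof, sigma = make_profile(tail_amp=0.9, tail_k=0.08, noise=0.004, seed=2)
    cfg = BMQuantConfig(monotone_tail=True)
    est_none = quantify_profile(prof, -11.0, -sigma, sigma, method="none", config=cfg)
    est_cub = quantify_profile(prof, -11.0, -sigma, sigma, method="cubic", config=cfg)
    truth = GAUSSIAN_FWHM_PER_SIGMA * sigma
    assert est_none.fwhm > est_cub.fwhm
    assert est_none.r_squared < est_cub.r_squared
    assert est_cub.fwhm == pytest.approx(truth, rel=0.06)


def test_quadrature_width_of_convolved_bm():
    """True 2.40 um BM seen through a 0.707 um PSF measures ~2.502 um."""
    prof, sigma = make_profile()
    est = quantify_profile(prof, -11.0, -sigma, sigma, method="none")
    assert est.fwhm == pytest.approx(np.hypot(2.40, 0.707), rel=0.01)


def test_correction_is_noop_without_tail():
    """With no tail the corrected estimate equals the uncorrected one within 1%.

    Uses the wide-band window configuration (deeper inner guard, monotone
    extrapolation clamp): for a band several times wider than the PSF the
    short default guard would leave part of the Gaussian flank inside the
    tail window.
    """
    prof, sigma = make_profile(tail_amp=0.0)
    cfg = BMQuantConfig(tail_start_offset=1.0, guard_inner_psf=2.0, monotone_tail=True)
    est_none = quantify_profile(prof, -11.0, -sigma, sigma, method="none", config=cfg)
    est_cub = quantify_profile(prof, -11.0, -sigma, sigma, method="cubic", config=cfg)
    assert est_cub.fwhm == pytest.approx(est_none.fwhm, rel=0.01)


def test_quantification_invariant_to_intensity_scale():
    prof, sigma = make_profile(tail_amp=0.6, noise=0.003, seed=5)
    scaled = DepthProfile(prof.z, prof.intensity * 123.0)
    a = quantify_profile(prof, -11.0, -sigma, sigma, method="cubic")
    b = quantify_profile(scaled, -11.0, -sigma, sigma, method="cubic")
    assert a.fwhm == pytest.approx(b.fwhm, rel=1e-6)


@pytest.mark.parametrize(
    "values, expected",
    [([2.0, 2.0, 2.0], 0.0), ([1.0, 3.0], np.sqrt(2.0) / 2.0)],
)
def test_cov_examples(values, expected):
    assert coefficient_of_variation(values) == pytest.approx(expected, abs=1e-12)


def test_cov_scale_invariance():
    x = [1.2, 3.4, 2.2, 5.1]
    assert coefficient_of_variation(x) == pytest.approx(
        coefficient_of_variation([7 * v for v in x])
    )


def test_cov_zero_mean_undefined():
    with pytest.raises(UndefinedCoVError):
        coefficient_of_variation([-1.0, 1.0])


def test_unknown_method_rejected():
    prof, sigma = make_profile()
    with pytest.raises(InvalidInputError):
        quantify_profile(prof, -11.0, -sigma, sigma, method="quartic")
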