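"""Monte Carlo photon transport through an RPE slab above Bruch's membrane.

The model is a 1-D pencil beam entering a homogeneous scattering slab
(the RPE, thickness ``rpe_thickness``) resting on a planar specular
reflector (Bruch's membrane, BM).  Photon packets propagate with
exponentially distributed free paths (rate ``mu_s``), are deflected by
Henyey–Greenstein scattering with anisotropy ``g``, and lose weight to
absorption (``mu_a``) along their path.  Packets reaching the BM plane
are either mirror-reflected with weight ``bm_reflectance`` or, in the
``absorbing_nonreflective`` mode, terminated — the latter run isolates
the RPE multiple-scattering tail that contaminates depths beyond BM.

Detected light is scored at the *apparent* depth implied by time of
flight,

    z_apparent = (total optical path length) / 2 - rpe_thickness,

so the ballistic BM echo lands exactly at z = 0 and the RPE occupies
z < 0.  The depth histogram is convolved with the Gaussian intensity
PSF of the system, and every contribution is classified by its
scattering history: ballistic (no scattering event), quasi-ballistic
(total accumulated deflection below a small-angle threshold), or
multiply scattered.

Scoring uses a local (next-event) estimator, the standard variance
reduction for narrow-aperture detection: at every scattering vertex the
expected contribution of (a) scattering directly into the acceptance
cone and escaping, and (b) scattering vertically down, reflecting off
BM and escaping, is added analytically, and the unscattered BM echo is
scored in closed form.  The recorded histogram is therefore the
expectation of the naive exit-within-cone tally, at far lower variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidInputError, NoDetectedPhotonsError, UnderSampledError
from .optics import AxialPSF
from .profile import DepthProfile

__all__ = ["LayeredMedium", "simulate_depth_profile", "tail_reference"]

#: accumulated-deflection threshold separating quasi-ballistic from
#: multiply scattered packets (degrees); affects only the diagnostic split.
QUASI_BALLISTIC_DEFLECTION_DEG = 10.0

_MIN_PHOTONS = 1000
_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVE = 0.1
_MAX_STEPS = 10000
_SPLIT = 8  # splitting factor at the first direction reversal
_CLASS_NAMES = ("ballistic", "quasi_ballistic", "multiple")


@dataclass(frozen=True)
class LayeredMedium:
    """Optical description of the RPE slab and the BM reflector.

    Defaults are order-of-magnitude values for the strongly scattering,
    moderately anisotropic melanosome-laden RPE at visible wavelengths;
    all are configuration-exposed and the downstream analysis is
    designed not to depend on their exact values.  ``bm_reflectance``
    acts as a relative weight only, since profiles are normalized
    before quantification.
    """

    rpe_thickness: float = 10.0  # µm
    mu_s: float = 0.3  # scattering coefficient, 1/µm
    g: float = 0.94  # Henyey-Greenstein anisotropy
    mu_a: float = 0.05  # absorption coefficient, 1/µm
    bm_mode: str = "reflective"  # or "absorbing_nonreflective"
    bm_reflectance: float = 0.003  # relative weight of the BM specular echo
    acceptance_half_angle: float = 5.0  # degrees

    def __post_init__(self) -> None:
        if self.rpe_thickness <= 0:
            raise InvalidInputError("rpe_thickness must be positive")
        if self.mu_s < 0 or self.mu_a < 0:
            raise InvalidInputError("mu_s and mu_a must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise InvalidInputError("anisotropy g must lie in (-1, 1)")
        if not 0.0 <= self.bm_reflectance <= 1.0:
            raise InvalidInputError("bm_reflectance must lie in [0, 1]")
        if self.bm_mode not in ("reflective", "absorbing_nonreflective"):
            raise InvalidInputError(f"unknown bm_mode: {self.bm_mode!r}")
        if not 0.0 < self.acceptance_half_angle <= 90.0:
            raise InvalidInputError("acceptance_half_angle must be in (0, 90] degrees")

    @classmethod
    def from_yaml(cls, path) -> "LayeredMedium":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        fields = {
            "rpe_thickness": self.rpe_thickness,
            "mu_s": self.mu_s,
            "g": self.g,
            "mu_a": self.mu_a,
            "bm_mode": self.bm_mode,
            "bm_reflectance": self.bm_reflectance,
            "acceptance_half_angle": self.acceptance_half_angle,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(fields, fh)


def _hg_costheta(g: float, xi: np.ndarray) -> np.ndarray:
    """Sample the Henyey-Greenstein polar deflection cosine."""
    if abs(g) < 1e-8:
        return 1.0 - 2.0 * xi
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def _hg_pdf(g: float, cos_theta: np.ndarray) -> np.ndarray:
    """Henyey-Greenstein phase function per steradian."""
    return (1.0 - g * g) / (4.0 * np.pi * (1.0 + g * g - 2.0 * g * cos_theta) ** 1.5)


def _scatter_directions(u: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors ``u`` by polar angle arccos(cos_t) and azimuth phi."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    near_vert = np.abs(uz) > 0.99999
    denom = np.sqrt(np.maximum(1e-24, 1.0 - uz**2))
    nx = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
    ny = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
    nz = -sin_t * cos_p * denom + uz * cos_t
    out = np.empty_like(u)
    out[:, 0] = np.where(near_vert, sin_t * cos_p, nx)
    out[:, 1] = np.where(near_vert, sin_t * sin_p, ny)
    out[:, 2] = np.where(near_vert, cos_t * np.sign(uz), nz)
    return out / np.sqrt(np.sum(out**2, axis=1))[:, None]


class _Tally:
    """Class-resolved weighted depth histogram."""

    def __init__(self, edges: np.ndarray, quasi_thresh: float) -> None:
        self.edges = edges
        self.quasi_thresh = quasi_thresh
        self.hist = {k: np.zeros(edges.size - 1) for k in _CLASS_NAMES}

    def add(self, z: np.ndarray, w: np.ndarray, n_scat: np.ndarray, cum_defl: np.ndarray) -> None:
        cls = np.where(n_scat == 0, 0, np.where(cum_defl < self.quasi_thresh, 1, 2))
        for ci, name in enumerate(_CLASS_NAMES):
            sel = cls == ci
            if np.any(sel):
                h, _ = np.histogram(z[sel], bins=self.edges, weights=w[sel])
                self.hist[name] += h


def simulate_depth_profile(
    medium: LayeredMedium,
    psf: AxialPSF,
    n_photons: int,
    seed: int,
    z_range: Tuple[float, float] = (-12.0, 8.0),
    grid_spacing: Optional[float] = None,
) -> DepthProfile:
    """Simulate the depth-resolved OCT signal of the RPE/BM complex.

    Returns a :class:`DepthProfile` on a uniform grid over ``z_range``
    (µm, BM echo at 0) whose intensity is the expected detected weight
    per depth bin convolved with the Gaussian intensity PSF, carrying
    the per-class (ballistic / quasi-ballistic / multiple) split.  Two
    runs with the same arguments and seed are bit-identical.
    """
    if n_photons < _MIN_PHOTONS:
        raise UnderSampledError(f"n_photons must be >= {_MIN_PHOTONS}")
    dz = psf.grid_spacing if grid_spacing is None else grid_spacing
    if dz > psf.intensity_fwhm / 2.0 + 1e-12:
        raise InvalidInputError("grid spacing must satisfy Nyquist for the PSF")

    rng = np.random.default_rng(seed)
    T = medium.rpe_thickness
    mu_t = medium.mu_s + medium.mu_a
    alpha = np.deg2rad(medium.acceptance_half_angle)
    omega = 2.0 * np.pi * (1.0 - np.cos(alpha))  # acceptance solid angle
    quasi_thresh = np.deg2rad(QUASI_BALLISTIC_DEFLECTION_DEG)
    reflective = medium.bm_mode == "reflective"

    edges = np.arange(z_range[0], z_range[1] + dz / 2, dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    tally = _Tally(edges, quasi_thresh)

    n = int(n_photons)
    # unscattered (ballistic) BM echo, scored in closed form
    if reflective and medium.bm_reflectance > 0:
        ball = n * medium.bm_reflectance * np.exp(-2.0 * T * mu_t)
        tally.add(np.array([0.0]), np.array([ball]), np.array([0]), np.array([0.0]))

    if medium.mu_s > 0:
        # photon-packet state (compacted to alive packets each step)
        x = np.zeros(n)  # depth below the top surface, in [0, T]
        u = np.zeros((n, 3))
        u[:, 2] = 1.0
        w = np.ones(n)
        path = np.zeros(n)
        n_scat = np.zeros(n, dtype=np.int64)
        cum_defl = np.zeros(n)
        was_reversed = np.zeros(n, dtype=bool)

        for _ in range(_MAX_STEPS):
            if x.size == 0:
                break
            s = rng.exponential(1.0 / medium.mu_s, x.size)
            # advance; handle boundary crossings (possibly repeated)
            alive = np.ones(x.size, dtype=bool)
            moving = alive.copy()
            while moving.any():
                uz = u[:, 2]
                with np.errstate(divide="ignore", invalid="ignore"):
                    d_bound = np.where(uz > 0, (T - x) / uz, np.where(uz < 0, -x / uz, np.inf))
                d_bound = np.maximum(d_bound, 0.0)
                finish = moving & (s < d_bound)
                if finish.any():
                    x[finish] += uz[finish] * s[finish]
                    path[finish] += s[finish]
                    w[finish] *= np.exp(-medium.mu_a * s[finish])
                    moving[finish] = False
                cross = moving.copy()
                if not cross.any():
                    break
                d = d_bound[cross]
                path[cross] += d
                w[cross] *= np.exp(-medium.mu_a * d)
                s[cross] -= d
                idx = np.nonzero(cross)[0]
                down = uz[idx] > 0
                at_bm = idx[down]
                at_top = idx[~down]
                if at_bm.size:
                    if reflective:
                        x[at_bm] = T
                        w[at_bm] *= medium.bm_reflectance
                        u[at_bm, 2] *= -1.0
                    else:
                        alive[at_bm] = False
                        moving[at_bm] = False
                if at_top.size:
                    # exits are not scored here: the local estimator at each
                    # scattering vertex already accounts for them in expectation
                    alive[at_top] = False
                    moving[at_top] = False

            if not alive.any():
                break
            x, u, w, path = x[alive], u[alive], w[alive], path[alive]
            n_scat, cum_defl, was_reversed = n_scat[alive], cum_defl[alive], was_reversed[alive]

            # --- local estimator at the scattering vertex ---
            uz = u[:, 2]
            esc = np.exp(-mu_t * x)  # unscattered escape through the top
            # (a) scatter straight up into the acceptance cone and escape
            p_up = _hg_pdf(medium.g, -uz)
            w_up = w * p_up * omega * esc
            z_up = (path + x) / 2.0 - T
            defl_up = cum_defl + np.arccos(np.clip(-uz, -1.0, 1.0))
            tally.add(z_up, w_up, n_scat + 1, defl_up)
            # (b) scatter straight down, specular BM bounce, escape
            if reflective and medium.bm_reflectance > 0:
                p_dn = _hg_pdf(medium.g, uz)
                atten = np.exp(-mu_t * (2.0 * T - x))
                w_dn = w * p_dn * omega * medium.bm_reflectance * atten
                z_dn = (path + (T - x) + T) / 2.0 - T
                defl_dn = cum_defl + np.arccos(np.clip(uz, -1.0, 1.0))
                tally.add(z_dn, w_dn, n_scat + 1, defl_dn)

            # --- sample the actual new direction ---
            cos_t = _hg_costheta(medium.g, rng.random(x.size))
            phi = 2.0 * np.pi * rng.random(x.size)
            u = _scatter_directions(u, cos_t, phi)
            n_scat = n_scat + 1
            cum_defl = cum_defl + np.arccos(np.clip(cos_t, -1.0, 1.0))

            # geometric splitting at the first direction reversal: packets
            # turning upward are rare but feed the multiple-scattering tail,
            # so each is split into _SPLIT copies of 1/_SPLIT the weight
            flip = (~was_reversed) & (u[:, 2] < 0.0)
            was_reversed = was_reversed | flip
            if _SPLIT > 1 and flip.any():
                w[flip] /= _SPLIT
                rep = _SPLIT - 1
                fi = np.nonzero(flip)[0]
                x = np.concatenate([x, np.tile(x[fi], rep)])
                u = np.concatenate([u, np.tile(u[fi], (rep, 1))])
                w = np.concatenate([w, np.tile(w[fi], rep)])
                path = np.concatenate([path, np.tile(path[fi], rep)])
                n_scat = np.concatenate([n_scat, np.tile(n_scat[fi], rep)])
                cum_defl = np.concatenate([cum_defl, np.tile(cum_defl[fi], rep)])
                was_reversed = np.concatenate([was_reversed, np.ones(rep * fi.size, dtype=bool)])

            # Russian roulette on low-weight packets
            low = w < _ROULETTE_THRESHOLD
            if low.any():
                il = np.nonzero(low)[0]
                survive = rng.random(il.size) < _ROULETTE_SURVIVE
                w[il[survive]] /= _ROULETTE_SURVIVE
                keep = np.ones(x.size, dtype=bool)
                keep[il[~survive]] = False
                x, u, w, path = x[keep], u[keep], w[keep], path[keep]
                n_scat, cum_defl, was_reversed = n_scat[keep], cum_defl[keep], was_reversed[keep]

    raw_total = sum(tally.hist.values())
    if raw_total.sum() == 0 and (medium.mu_s > 0 or (reflective and medium.bm_reflectance > 0)):
        raise NoDetectedPhotonsError("no photon packet reached the detector")

    sigma_bins = psf.intensity_sigma / dz
    smoothed = {k: gaussian_filter1d(h, sigma_bins, mode="constant") for k, h in tally.hist.items()}
    total = sum(smoothed.values())
    return DepthProfile(
        z=centers,
        intensity=total,
        n_photons=n,
        seed=seed,
        path_class_split=smoothed,
    )


def tail_reference(
    medium: LayeredMedium,
    psf: AxialPSF,
    n_photons: int,
    seed: int,
    z_range: Tuple[float, float] = (-12.0, 8.0),
    grid_spacing: Optional[float] = None,
) -> DepthProfile:
    """Multiple-scattering tail isolated by a fully absorbing, nonreflective BM.

    Convenience wrapper forcing ``bm_mode="absorbing_nonreflective"``; the
    result is the in-silico ground-truth tail to subtract from a matched
    reflective-BM run.
    """
    absorbing = replace(medium, bm_mode="absorbing_nonreflective")
    try:
        return simulate_depth_profile(absorbing, psf, n_photons, seed, z_range, grid_spacing)
    except NoDetectedPhotonsError:
        # no scattering -> the tail is identically zero
        dz = psf.grid_spacing if grid_spacing is None else grid_spacing
        edges = np.arange(z_range[0], z_range[1] + dz / 2, dz)
        centers = 0.5 * (edges[:-1] + edges[1:])
        zeros = np.zeros(centers.size)
        return DepthProfile(
            z=centers,
            intensity=zeros,
            n_photons=int(n_photons),
            seed=seed,
            path_class_split={k: zeros.copy() for k in _CLASS_NAMES},
        )
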