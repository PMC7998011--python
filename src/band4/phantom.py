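"""Synthetic macula generator: seeded radial-scan sets with ground truth.

The phantom is a radially symmetric parametric macula rendered into
linear-intensity B-scans the way a visible-light OCT system would see
it: eight outer-retinal boundaries (ILM, ELM, inner EZ, inner
photoreceptor OST, apical RPE, inner BM, BM peak, outer BM), a foveal
pit (minimal ILM-to-ELM thickness at the fovea), an RPE whose thickness
plateaus centrally and falls with eccentricity, an apically weighted
RPE interior intensity decaying with depth, a thin Gaussian Bruch's
membrane (BM) band, an exponential RPE multiple-scattering tail
extending past BM, a dim choriocapillaris plateau beyond BM, Gaussian
axial PSF blur, and fully developed speckle reduced by slow-axis frame
averaging.

The default cohort is calibrated so that the *true* area-weighted RPE
thickness means over the standard 0.75 / 2.25 / 4.5 mm circles are
11.13, 10.55 and 9.56 µm, the true BM FWHM is 2.40 µm (2.50 µm once
convolved with the 0.707 µm intensity PSF), and between-eye spreads
reproduce cohort standard deviations of 0.88 µm (RPE, central disc) and
0.16 µm (BM).

Hyperreflective bands with resolvable substructure (EZ, OST, the RPE
interior) are rendered as top-hat / windowed profiles so their
operational boundaries are the maximal-gradient loci at the rendered
edges; BM, which the system barely resolves, is rendered as a Gaussian
and its inner/outer boundaries are *defined* as the inflection points
of the PSF-convolved band (peak ∓ one convolved sigma) — the positions
a gradient-based segmentation detects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidInputError, OutOfFieldError
from .optics import AxialPSF, sigma_from_gaussian_fwhm
from .profile import DepthProfile

__all__ = [
    "EyePhantom",
    "ScanProtocol",
    "CohortSpec",
    "GroundTruth",
    "RadialScanSet",
    "BOUNDARY_ORDER",
    "base_rpe_thickness",
    "default_phantom",
    "default_cohort_spec",
    "draw_cohort",
    "render_ascan",
    "render_bscan",
    "render_radial_set",
]

BOUNDARY_ORDER = (
    "ILM",
    "ELM",
    "EZ_inner",
    "PR_OST_inner",
    "RPE_apical",
    "BM_inner",
    "BM_peak",
    "BM_outer",
)

# --- calibrated true RPE thickness profile -------------------------------
# plateau value (µm) inside the foveal disc, and the cosine-ramp shape
# parameters solved so that area-weighted means over the 0.75 mm disc and
# the 0.75-2.25 / 2.25-4.5 mm annuli are 11.13 / 10.55 / 9.56 µm.
_RPE_PEAK = 11.13
_RPE_FLOOR = 9.0765405558
_RPE_SHAPE_P = 0.5721737585
_RPE_R0 = 0.375  # plateau radius, mm
_RPE_REND = 3.0  # eccentricity where the floor is reached, mm


def base_rpe_thickness(r_mm) -> np.ndarray:
    """True RPE thickness (µm) versus eccentricity (mm), cohort average.

    Plateau of 11.13 µm inside r <= 0.375 mm, then a smooth monotone
    cosine-ramp decrease to a floor at r = 3 mm, constant beyond.
    """
    r = np.abs(np.asarray(r_mm, float))
    u = np.clip((r - _RPE_R0) / (_RPE_REND - _RPE_R0), 0.0, 1.0)
    s = 0.5 * (1.0 + np.cos(np.pi * u**_RPE_SHAPE_P))
    return _RPE_FLOOR + (_RPE_PEAK - _RPE_FLOOR) * s


@dataclass
class ScanProtocol:
    """Acquisition geometry of the hybrid radial-raster protocol."""

    n_angles: int = 6
    angular_step: float = 30.0  # degrees
    ascans_per_line: int = 840
    fov: float = 15.0  # degrees
    frames_for_averaging: int = 30
    axial_pixel: float = 0.35  # µm
    mm_per_degree: float = 0.3
    centration_error: Tuple[float, float] = (0.0, 0.0)  # mm
    depth_extent: float = 300.0  # µm of rendered depth

    def __post_init__(self) -> None:
        if min(self.n_angles, self.ascans_per_line, self.frames_for_averaging) < 1:
            raise InvalidInputError("counts must be >= 1")
        if self.fov <= 0 or self.axial_pixel <= 0 or self.mm_per_degree <= 0:
            raise InvalidInputError("fov, axial_pixel and mm_per_degree must be positive")

    @property
    def n_rows(self) -> int:
        return int(round(self.depth_extent / self.axial_pixel))

    @property
    def column_positions_mm(self) -> np.ndarray:
        """Signed distance (mm) of each column from the scan-line center."""
        w = self.ascans_per_line
        half_mm = self.fov / 2.0 * self.mm_per_degree
        return np.linspace(-half_mm, half_mm, w)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angular_step


@dataclass
class EyePhantom:
    """One synthetic eye: anatomy, reflectivity and per-eye perturbations.

    Depths grow downward from the image top (µm); the BM peak sits at
    ``bm_peak_depth_um + bm_bow_um_per_mm2 * r^2``.  ``eye_scale_factor``
    multiplies every thickness above BM; ``bm_true_fwhm`` is the true
    (pre-PSF) Gaussian FWHM of the BM band.
    """

    eye_id: str = "eye00"
    eye_scale_factor: float = 1.0
    bm_true_fwhm: float = 2.40  # µm
    rpe_attenuation: float = 0.15  # volumetric attenuation, 1/µm (one way)
    # second interior component: a deeper organelle band (melanolipofuscin /
    # mitochondria) so the interior is not a single exponential
    rpe_interior_gauss_frac: float = 0.0
    rpe_interior_gauss_center_um: float = 3.0
    rpe_interior_gauss_sigma_um: float = 2.5
    tail_amplitude: float = 1.50  # linear intensity at the apical RPE
    tail_decay: float = 0.08  # 1/µm
    chorio_amplitude: float = 0.12
    chorio_offset_um: float = 1.5  # choriocapillaris onset below the outer BM
    centration_error: Tuple[float, float] = (0.0, 0.0)  # mm, scan-center offset
    tilt_um_per_mm: Tuple[float, float] = (0.0, 0.0)  # retina tilt plane gradient
    bm_peak_depth_um: float = 283.0
    bm_bow_um_per_mm2: float = 0.6
    band_reflectivities: Dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.01,
            "inner_retina": 0.06,
            "ILM": 0.80,
            "ELM": 0.50,
            "EZ": 1.60,
            "outer_segment": 0.08,
            "PR_OST": 1.00,
            "subsurface_gap": 0.08,
            "RPE_apical": 1.30,
            "BM": 0.90,
        }
    )

    # fixed band thicknesses (µm, before eye scaling)
    ilm_band_um: float = 2.0
    elm_band_um: float = 2.0
    ez_band_um: float = 3.0
    prost_band_um: float = 3.0
    prost_to_rpe_um: float = 6.0
    elm_to_ez_um: float = 12.0

    def os_length(self, r_mm) -> np.ndarray:
        """Photoreceptor outer-segment length (µm), longest at the fovea."""
        r = np.abs(np.asarray(r_mm, float))
        return 28.0 + 8.0 * np.exp(-((r / 1.2) ** 2))

    def inner_retina_thickness(self, r_mm) -> np.ndarray:
        """ILM-to-ELM distance (µm): the foveal pit, thinnest at r = 0."""
        r = np.abs(np.asarray(r_mm, float))
        return 60.0 + 90.0 * (1.0 - np.exp(-((r / 0.9) ** 2)))

    def rpe_thickness(self, r_mm) -> np.ndarray:
        """True apical-RPE-to-inner-BM distance (µm) for this eye."""
        return base_rpe_thickness(r_mm) * self.eye_scale_factor

    def measured_bm_sigma(self, psf: AxialPSF) -> float:
        """Sigma of the PSF-convolved BM band (µm)."""
        s_bm = sigma_from_gaussian_fwhm(self.bm_true_fwhm)
        return float(np.hypot(s_bm, psf.intensity_sigma))

    def boundary_depths(self, r_mm, psf: AxialPSF) -> Dict[str, np.ndarray]:
        """Depths (µm from image top) of the eight boundaries at ``r_mm``."""
        r = np.abs(np.asarray(r_mm, float))
        k = self.eye_scale_factor
        bm_peak = self.bm_peak_depth_um + self.bm_bow_um_per_mm2 * r**2
        s_meas = self.measured_bm_sigma(psf)
        bm_inner = bm_peak - s_meas
        bm_outer = bm_peak + s_meas
        rpe_apical = bm_inner - self.rpe_thickness(r)
        prost_inner = rpe_apical - self.prost_to_rpe_um * k
        ez_inner = prost_inner - self.os_length(r) * k
        elm = ez_inner - self.elm_to_ez_um * k
        ilm = elm - self.inner_retina_thickness(r) * k
        return {
            "ILM": ilm,
            "ELM": elm,
            "EZ_inner": ez_inner,
            "PR_OST_inner": prost_inner,
            "RPE_apical": rpe_apical,
            "BM_inner": bm_inner,
            "BM_peak": bm_peak,
            "BM_outer": bm_outer,
        }


@dataclass
class CohortSpec:
    """Size, seed and between-eye variability of a synthetic cohort."""

    n_eyes: int = 19
    seed: int = 0
    between_eye_sd: float = 0.88 / 11.13  # fractional SD of eye_scale_factor
    bm_fwhm_sd: float = 0.16 * (2.40 / 2.50) / 2.40  # fractional SD of true BM FWHM
    tail_amplitude_sd: float = 0.30  # fractional SD of the tail amplitude
    tilt_sd_um_per_mm: float = 3.0  # per-axis SD of the retinal tilt gradient
    chorio_sd: float = 0.30
    centration_sd_mm: float = 0.03  # per-axis SD of the scan-center offset
    phantom_defaults: EyePhantom = field(default_factory=EyePhantom)

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise InvalidInputError("n_eyes must be >= 1")
        if self.between_eye_sd < 0:
            raise InvalidInputError("between_eye_sd must be >= 0")


def default_cohort_spec(n_eyes: int = 19, seed: int = 0) -> CohortSpec:
    """Cohort defaults calibrated to the printed sector statistics.

    True sector means are 11.13 / 10.55 / 9.56 µm (central disc, inner
    annulus, outer annulus), the true BM FWHM is 2.40 µm (≈2.50 µm after
    PSF convolution), and between-eye spreads reproduce the cohort SDs
    of 0.88 µm (RPE) and 0.16 µm (measured BM FWHM).
    """
    return CohortSpec(n_eyes=n_eyes, seed=seed)


def draw_cohort(spec: CohortSpec) -> List[EyePhantom]:
    """Draw the per-eye perturbations of a cohort, deterministically.

    Multiplicative per-eye factors are drawn as clipped Gaussians and
    renormalized to unit cohort mean, so the cohort-level truth equals
    the calibrated population values while the spread matches the
    requested SDs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_eyes

    def factors(sd: float) -> np.ndarray:
        f = 1.0 + sd * np.clip(rng.standard_normal(n), -2.5, 2.5)
        f = np.maximum(f, 0.2)
        return f / f.mean()

    scale = factors(spec.between_eye_sd)
    bm = factors(spec.bm_fwhm_sd)
    tail = factors(spec.tail_amplitude_sd)
    chorio = factors(spec.chorio_sd)
    cent = rng.normal(0.0, spec.centration_sd_mm, size=(n, 2))
    tilt = rng.normal(0.0, spec.tilt_sd_um_per_mm, size=(n, 2))
    base = spec.phantom_defaults
    eyes = []
    for i in range(n):
        eyes.append(
            replace(
                base,
                eye_id=f"eye{i:02d}",
                eye_scale_factor=float(scale[i]),
                bm_true_fwhm=base.bm_true_fwhm * float(bm[i]),
                tail_amplitude=base.tail_amplitude * float(tail[i]),
                chorio_amplitude=base.chorio_amplitude * float(chorio[i]),
                centration_error=(float(cent[i, 0]), float(cent[i, 1])),
                tilt_um_per_mm=(float(tilt[i, 0]), float(tilt[i, 1])),
            )
        )
    return eyes


@dataclass
class GroundTruth:
    """Exact rendering geometry of one radial scan set."""

    contours_px: Dict[str, np.ndarray]  # boundary -> (n_angles, n_cols) subpixel rows
    eccentricity_mm: np.ndarray  # (n_angles, n_cols) distance from the true fovea
    signed_position_mm: np.ndarray  # (n_angles, n_cols) signed position along each line
    fovea_offset_mm: Tuple[float, float]  # scan center minus true fovea
    rpe_thickness_um: np.ndarray  # (n_angles, n_cols) true RPE thickness
    bm_true_fwhm: float
    bm_measured_fwhm: float  # after PSF convolution

    def contours_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for name, arr in self.contours_px.items():
            for a in range(arr.shape[0]):
                for c in range(arr.shape[1]):
                    rows.append((a, c, name, arr[a, c]))
        pd.DataFrame(rows, columns=["angle_index", "column_index", "boundary_name", "position_px"]).to_csv(
            path, index=False
        )


@dataclass
class RadialScanSet:
    """Six averaged B-scans at fixed angular increments, with metadata."""

    images: np.ndarray  # (n_angles, n_rows, n_cols) linear intensity
    protocol: ScanProtocol
    psf: AxialPSF
    eye_id: str = ""
    seed: Optional[int] = None

    @property
    def angles_deg(self) -> np.ndarray:
        return self.protocol.angles_deg

    def to_tiff(self, path, metadata_path=None) -> None:
        """32-bit float TIFF stack plus a JSON metadata sidecar."""
        import tifffile

        tifffile.imwrite(path, self.images.astype(np.float32))
        meta = {
            "eye_id": self.eye_id,
            "seed": self.seed,
            "n_angles": self.protocol.n_angles,
            "angular_step_deg": self.protocol.angular_step,
            "ascans_per_line": self.protocol.ascans_per_line,
            "fov_deg": self.protocol.fov,
            "frames_for_averaging": self.protocol.frames_for_averaging,
            "axial_pixel_um": self.protocol.axial_pixel,
            "mm_per_degree": self.protocol.mm_per_degree,
            "psf_field_fwhm_um": self.psf.field_fwhm,
        }
        if metadata_path is None:
            metadata_path = str(path) + ".json"
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_tiff(cls, path, metadata_path=None) -> "RadialScanSet":
        import tifffile

        if metadata_path is None:
            metadata_path = str(path) + ".json"
        with open(metadata_path) as fh:
            meta = json.load(fh)
        proto = ScanProtocol(
            n_angles=meta["n_angles"],
            angular_step=meta["angular_step_deg"],
            ascans_per_line=meta["ascans_per_line"],
            fov=meta["fov_deg"],
            frames_for_averaging=meta["frames_for_averaging"],
            axial_pixel=meta["axial_pixel_um"],
            mm_per_degree=meta["mm_per_degree"],
        )
        psf = AxialPSF(field_fwhm=meta["psf_field_fwhm_um"], grid_spacing=meta["axial_pixel_um"])
        return cls(
            images=np.asarray(tifffile.imread(path), float),
            protocol=proto,
            psf=psf,
            eye_id=meta.get("eye_id", ""),
            seed=meta.get("seed"),
        )


# --- rendering -----------------------------------------------------------


def _coverage(z: np.ndarray, top: np.ndarray, bottom: np.ndarray) -> np.ndarray:
    """Fraction of each axial pixel covered by [top, bottom] (anti-aliased).

    ``z`` is (n_rows, 1); ``top``/``bottom`` broadcast over columns.
    """
    dz = z[1, 0] - z[0, 0]
    lo = np.maximum(top, z - dz / 2.0)
    hi = np.minimum(bottom, z + dz / 2.0)
    return np.clip((hi - lo) / dz, 0.0, 1.0)


def _render_noise_free(
    phantom: EyePhantom,
    r_mm: np.ndarray,
    psf: AxialPSF,
    protocol: ScanProtocol,
    depth_offset_um=0.0,
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Noise-free PSF-convolved image for columns at eccentricities ``r_mm``.

    ``depth_offset_um`` shifts the whole anatomy axially (sub-pixel
    acquisition phase).  Returns (image (n_rows, n_cols), boundary
    depths in µm, offset included).
    """
    refl = phantom.band_reflectivities
    k = phantom.eye_scale_factor
    n_rows = protocol.n_rows
    z = (np.arange(n_rows, dtype=float) * protocol.axial_pixel)[:, None]
    b = phantom.boundary_depths(r_mm, psf)
    if np.any(np.asarray(depth_offset_um) != 0.0):
        b = {name: v + depth_offset_um for name, v in b.items()}

    img = np.full((n_rows, r_mm.size), refl["background"])
    # inner retina fill between ILM and ELM, dim
    img += (refl["inner_retina"] - refl["background"]) * _coverage(z, b["ILM"], b["ELM"])
    # thin hyperreflective bands rendered as top-hats (edges = boundaries)
    img += refl["ILM"] * _coverage(z, b["ILM"], b["ILM"] + phantom.ilm_band_um * k)
    img += refl["ELM"] * _coverage(z, b["ELM"], b["ELM"] + phantom.elm_band_um * k)
    img += refl["EZ"] * _coverage(z, b["EZ_inner"], b["EZ_inner"] + phantom.ez_band_um * k)
    img += refl["outer_segment"] * _coverage(
        z, b["EZ_inner"] + phantom.ez_band_um * k, b["PR_OST_inner"]
    )
    img += refl["PR_OST"] * _coverage(
        z, b["PR_OST_inner"], b["PR_OST_inner"] + phantom.prost_band_um * k
    )
    img += refl["subsurface_gap"] * _coverage(
        z, b["PR_OST_inner"] + phantom.prost_band_um * k, b["RPE_apical"]
    )
    # apically weighted RPE interior: melanosome exponential plus a deeper
    # organelle band, normalized to 1 at the apical edge
    depth_into_rpe = np.clip(z - b["RPE_apical"], 0.0, None)
    rpe_block = _coverage(z, b["RPE_apical"], b["BM_inner"])
    f = phantom.rpe_interior_gauss_frac
    g0 = phantom.rpe_interior_gauss_center_um
    gs = phantom.rpe_interior_gauss_sigma_um
    gauss_norm = np.exp(-(g0**2) / (2 * gs**2))
    interior = (1.0 - f) * np.exp(-2.0 * phantom.rpe_attenuation * depth_into_rpe)
    interior += f * np.exp(-((depth_into_rpe - g0) ** 2) / (2 * gs**2))
    interior /= (1.0 - f) + f * gauss_norm  # mixture equals 1 at d = 0
    img += refl["RPE_apical"] * interior * rpe_block
    # Bruch's membrane: thin Gaussian band (pre-PSF sigma)
    s_bm = sigma_from_gaussian_fwhm(phantom.bm_true_fwhm)
    img += refl["BM"] * np.exp(-((z - b["BM_peak"]) ** 2) / (2.0 * s_bm**2))
    # multiple-scattering tail from the apical RPE outward, past BM
    past = np.clip(z - b["RPE_apical"], 0.0, None)
    img += phantom.tail_amplitude * np.exp(-phantom.tail_decay * past) * (z >= b["RPE_apical"])
    # choriocapillaris plateau outer to BM
    img += phantom.chorio_amplitude * _coverage(
        z, b["BM_outer"] + phantom.chorio_offset_um, np.full_like(r_mm, 1e9)
    )

    # axial PSF blur; BM band rendered pre-PSF so its convolved sigma is
    # hypot(s_bm, psf sigma) = the operational band width
    img = gaussian_filter1d(img, psf.intensity_sigma / protocol.axial_pixel, axis=0, mode="nearest")
    return img, b


def render_ascan(
    phantom: EyePhantom,
    eccentricity_mm: float,
    psf: AxialPSF,
    protocol: ScanProtocol,
    seed: int,
) -> DepthProfile:
    """Render a single A-scan at the given eccentricity.

    Speckle is fully developed (unit-mean exponential multiplicative
    intensity noise, independent across the ``frames_for_averaging``
    frames); the returned profile is the frame average, drawn directly
    from the equivalent Gamma(n_frames, I/n_frames) distribution.
    """
    half_field = protocol.fov * protocol.mm_per_degree  # generous bound
    if abs(eccentricity_mm) > half_field:
        raise OutOfFieldError(f"eccentricity {eccentricity_mm} mm outside the modeled field")
    r = np.array([abs(float(eccentricity_mm))])
    img, _ = _render_noise_free(phantom, r, psf, protocol)
    rng = np.random.default_rng(seed)
    noisy = _apply_speckle(img, protocol.frames_for_averaging, rng)
    z = np.arange(img.shape[0], dtype=float) * protocol.axial_pixel
    return DepthProfile(z, noisy[:, 0], seed=seed)


def _apply_speckle(img: np.ndarray, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Average of ``n_frames`` i.i.d. fully developed speckle realizations.

    The mean of n independent Exp(mean=I) draws is Gamma(n, I/n), which
    is sampled directly.
    """
    return rng.gamma(shape=float(n_frames), scale=img / float(n_frames))


def render_bscan(
    phantom: EyePhantom,
    angle_deg: float,
    psf: AxialPSF,
    protocol: ScanProtocol,
    rng: np.random.Generator,
    speckle: bool = True,
) -> Tuple[np.ndarray, Dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Render one averaged B-scan along a radial line.

    Returns (image, contours in µm, eccentricity per column, signed
    position per column).  The scan line passes through the scan center
    (true fovea plus the phantom's centration error).
    """
    s = protocol.column_positions_mm
    th = np.deg2rad(angle_deg)
    cx, cy = phantom.centration_error
    px = cx + s * np.cos(th)
    py = cy + s * np.sin(th)
    r = np.hypot(px, py)
    # random sub-pixel acquisition phase plus the eye's tilt plane: a real
    # scanner never aligns its pixel grid to the anatomy, and the retina is
    # never perfectly flat in the scan frame; a fixed phase would lock
    # pixel-grid localization errors coherently across columns and eyes
    gxt, gyt = phantom.tilt_um_per_mm
    offset = float(rng.uniform(0.0, protocol.axial_pixel)) + gxt * px + gyt * py
    img, contours = _render_noise_free(phantom, r, psf, protocol, depth_offset_um=offset)
    if speckle:
        img = _apply_speckle(img, protocol.frames_for_averaging, rng)
    return img, contours, r, s


def render_radial_set(
    cohort_or_eye: Union[EyePhantom, CohortSpec],
    protocol: Optional[ScanProtocol] = None,
    seed: int = 0,
    psf: Optional[AxialPSF] = None,
    speckle: bool = True,
):
    """Render the full radial protocol for one eye (or each eye of a cohort).

    For an :class:`EyePhantom` returns ``(RadialScanSet, GroundTruth)``;
    for a :class:`CohortSpec` returns a list of such pairs, with per-eye
    sub-seeds derived from ``seed``.
    """
    protocol = protocol or ScanProtocol()
    psf = psf or AxialPSF(field_fwhm=1.0, grid_spacing=min(0.05, protocol.axial_pixel))

    if isinstance(cohort_or_eye, CohortSpec):
        eyes = draw_cohort(cohort_or_eye)
        seeds = np.random.SeedSequence(seed).spawn(len(eyes))
        out = []
        for eye, ss in zip(eyes, seeds):
            sub = int(ss.generate_state(1)[0] % (2**31))
            out.append(render_radial_set(eye, protocol, seed=sub, psf=psf, speckle=speckle))
        return out

    phantom = cohort_or_eye
    rng = np.random.default_rng(seed)
    n_rows = protocol.n_rows
    w = protocol.ascans_per_line
    images = np.empty((protocol.n_angles, n_rows, w))
    contours_px = {name: np.empty((protocol.n_angles, w)) for name in BOUNDARY_ORDER}
    ecc = np.empty((protocol.n_angles, w))
    pos = np.empty((protocol.n_angles, w))
    for a, ang in enumerate(protocol.angles_deg):
        img, contours, r, s = render_bscan(phantom, ang, psf, protocol, rng, speckle=speckle)
        images[a] = img
        ecc[a], pos[a] = r, s
        for name in BOUNDARY_ORDER:
            contours_px[name][a] = contours[name] / protocol.axial_pixel
    gt = GroundTruth(
        contours_px=contours_px,
        eccentricity_mm=ecc,
        signed_position_mm=pos,
        fovea_offset_mm=phantom.centration_error,
        rpe_thickness_um=phantom.rpe_thickness(ecc),
        bm_true_fwhm=phantom.bm_true_fwhm,
        bm_measured_fwhm=float(
            np.hypot(phantom.bm_true_fwhm, psf.intensity_fwhm)
        ),
    )
    return RadialScanSet(images=images, protocol=protocol, psf=psf, eye_id=phantom.eye_id, seed=seed), gt


def default_phantom() -> EyePhantom:
    """The population-average eye."""
    return EyePhantom()
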