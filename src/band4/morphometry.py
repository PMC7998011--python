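"""Thickness morphometry: fovea centration, sector maps, proportional fits.

Thickness samples live on the six radial scan lines; sector statistics
weight each sample by the annular area it represents (weight ∝ |r|·Δr·Δθ)
over the standard 0.75 / 2.25 / 4.5 mm circles split into
nasal/temporal/superior/inferior quadrants at the ±45° diagonals.

Three complementary centration strategies guard against radial-scan
alignment error: (1) recenter each B-scan at its own minimal
ILM-to-band-1 thickness; (2) estimate a 2-D foveal position from all
six lines and reinterpolate onto a radial grid centered there; (3)
avoid eccentricity altogether by plotting thickness against the inner
band 2 → outer band 4 thickness, an anatomical eccentricity proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RBFInterpolator
from scipy.ndimage import uniform_filter1d
from scipy.stats import binned_statistic, binned_statistic_2d

from .errors import (
    DegenerateFitError,
    EmptyInputError,
    InvalidInputError,
    MissingBoundaryError,
    MissingCoverageError,
)
from .errors import UnreliableCenterWarning
from .segmentation import BoundarySet

__all__ = [
    "SectorGrid",
    "ThicknessSamples",
    "SectorStats",
    "ProportionalFit",
    "layer_thickness",
    "find_fovea_method1",
    "find_fovea_method2",
    "eccentricity_proxy",
    "sector_average",
    "cohort_sector_stats",
    "proportional_fit",
    "thickness_histogram2d",
]


@dataclass(frozen=True)
class SectorGrid:
    """Concentric 0.75 / 2.25 / 4.5 mm circles with N/T/S/I quadrants."""

    radii_mm: Tuple[float, float, float] = (0.375, 1.125, 2.25)
    quadrant_names: Tuple[str, str, str, str] = ("T", "S", "N", "I")  # centered on 0/90/180/270°

    @property
    def region_names(self) -> List[str]:
        names = ["C"]
        for ring in ("inner", "outer"):
            for q in self.quadrant_names:
                names.append(f"{ring}_{q}")
        return names

    def assign(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Region label per sample ('' = outside the outer circle)."""
        r = np.hypot(x_mm, y_mm)
        theta = np.degrees(np.arctan2(y_mm, x_mm)) % 360.0
        quad_idx = (((theta + 45.0) % 360.0) / 90.0).astype(int)  # 0=T,1=S,2=N,3=I
        out = np.full(r.shape, "", dtype=object)
        out[r <= self.radii_mm[0]] = "C"
        inner = (r > self.radii_mm[0]) & (r <= self.radii_mm[1])
        outer = (r > self.radii_mm[1]) & (r <= self.radii_mm[2])
        for qi, q in enumerate(self.quadrant_names):
            out[inner & (quad_idx == qi)] = f"inner_{q}"
            out[outer & (quad_idx == qi)] = f"outer_{q}"
        return out


@dataclass
class ThicknessSamples:
    """Per-column thickness values on the radial scan lines.

    ``x_mm`` / ``y_mm`` are sample positions relative to the assumed
    fovea; ``value_um`` the thickness; ``ds_mm`` the along-line sample
    spacing (for area weights).
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    value_um: np.ndarray
    ds_mm: float
    label: str = ""
    angle_deg: Optional[np.ndarray] = None  # scan-line orientation per sample

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, float).ravel()
        self.y_mm = np.asarray(self.y_mm, float).ravel()
        self.value_um = np.asarray(self.value_um, float).ravel()
        if not (self.x_mm.size == self.y_mm.size == self.value_um.size):
            raise InvalidInputError("coordinate and value arrays must match")
        if self.angle_deg is not None:
            self.angle_deg = np.asarray(self.angle_deg, float).ravel()
            if self.angle_deg.size != self.x_mm.size:
                raise InvalidInputError("angle_deg must match sample count")

    @property
    def r_mm(self) -> np.ndarray:
        return np.hypot(self.x_mm, self.y_mm)

    def recentered(self, x0: float, y0: float) -> "ThicknessSamples":
        return ThicknessSamples(
            self.x_mm - x0, self.y_mm - y0, self.value_um, self.ds_mm, self.label, self.angle_deg
        )

    def area_weights(self) -> np.ndarray:
        """Annular-area weight per sample: |r dr| along the scan line.

        For a line of direction d̂ the radius Jacobian is |dr/ds| = |(p·d̂)|/r,
        so |r dr| = |p·d̂| ds; without line orientations the on-center
        approximation |r| ds is used.
        """
        if self.angle_deg is None:
            return np.maximum(self.r_mm, 1e-6) * self.ds_mm
        th = np.deg2rad(self.angle_deg)
        proj = np.abs(self.x_mm * np.cos(th) + self.y_mm * np.sin(th))
        return np.maximum(proj, 1e-6) * self.ds_mm


@dataclass
class SectorStats:
    """Area-weighted mean thickness per sector region of one eye."""

    region_means: Dict[str, float]
    grid: SectorGrid

    def ring_means(self) -> Dict[str, float]:
        """Area-weighted means over the disc and the two annuli."""
        g = self.grid
        r0, r1, r2 = g.radii_mm
        quad_area_inner = (r1**2 - r0**2) / 4.0
        quad_area_outer = (r2**2 - r1**2) / 4.0
        out = {"central_disc": self.region_means["C"]}
        for ring, area in (("inner", quad_area_inner), ("outer", quad_area_outer)):
            vals = [self.region_means[f"{ring}_{q}"] for q in g.quadrant_names]
            out[f"{ring}_annulus"] = float(np.mean(vals))  # equal-area quadrants
        return out

    def macular_mean(self) -> float:
        """Area-weighted mean over all nine regions (the full 4.5 mm disc)."""
        g = self.grid
        r0, r1, r2 = g.radii_mm
        areas = {"C": r0**2}
        for q in g.quadrant_names:
            areas[f"inner_{q}"] = (r1**2 - r0**2) / 4.0
            areas[f"outer_{q}"] = (r2**2 - r1**2) / 4.0
        tot = sum(areas.values())
        return float(sum(self.region_means[k] * a for k, a in areas.items()) / tot)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in self.region_means.items()], columns=["region", "mean_um"]
        )


def layer_thickness(
    boundaries: BoundarySet,
    top: str,
    bottom: str,
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    ds_mm: float,
    angle_deg: Optional[float] = None,
) -> ThicknessSamples:
    """Per-column thickness (µm) between two contours, with positions."""
    t = boundaries.depth_um(bottom) - boundaries.depth_um(top)
    ok = ~boundaries.mask
    return ThicknessSamples(
        np.asarray(x_mm)[ok], np.asarray(y_mm)[ok], t[ok], ds_mm, label=f"{top}->{bottom}",
        angle_deg=np.full(int(ok.sum()), angle_deg) if angle_deg is not None else None,
    )


def _smooth_mm(values: np.ndarray, window_mm: float, ds_mm: float) -> np.ndarray:
    n = max(int(round(window_mm / ds_mm)), 1)
    return uniform_filter1d(values, size=n, mode="nearest")


def find_fovea_method1(
    boundaries: BoundarySet,
    smooth_window_mm: float = 0.25,
    ds_mm: float = 15.0 * 0.3 / 839.0,
) -> int:
    """Column index of the minimal (smoothed) ILM-to-band-1 thickness.

    The B-scan should be recentered so this column becomes the center.
    A minimum at the scan edge triggers an unreliable-center warning.
    """
    t = boundaries.depth_um("ELM") - boundaries.depth_um("ILM")
    ts = _smooth_mm(t, smooth_window_mm, ds_mm)
    idx = int(np.argmin(ts))
    guard = max(int(0.05 * ts.size), 2)
    if idx < guard or idx > ts.size - 1 - guard:
        warnings.warn("foveal minimum at the scan edge", UnreliableCenterWarning)
    return idx


def find_fovea_method2(
    samples: ThicknessSamples,
    search_radius_mm: float = 1.0,
    grid_step_mm: float = 0.01,
    rbf_subsample: int = 8,
    smoothing: float = 1.0,
) -> Tuple[float, float]:
    """2-D foveal position from ILM-to-band-1 thickness over all lines.

    Fits a smooth thin-plate-spline surface to the (subsampled) samples
    and returns the position of its minimum inside the central search
    disc.  A minimizer outside the central 2 degrees (0.6 mm) triggers
    an unreliable-center warning.
    """
    pts = np.column_stack([samples.x_mm, samples.y_mm])[::rbf_subsample]
    vals = samples.value_um[::rbf_subsample]
    if pts.shape[0] < 10:
        raise EmptyInputError("too few samples for a foveal surface fit")
    rbf = RBFInterpolator(pts, vals, kernel="thin_plate_spline", smoothing=smoothing)
    g = np.arange(-search_radius_mm, search_radius_mm + grid_step_mm / 2, grid_step_mm)
    gx, gy = np.meshgrid(g, g)
    inside = np.hypot(gx, gy) <= search_radius_mm
    surf = np.full(gx.shape, np.inf)
    surf[inside] = rbf(np.column_stack([gx[inside], gy[inside]]))
    i, j = np.unravel_index(np.argmin(surf), surf.shape)
    x0, y0 = float(gx[i, j]), float(gy[i, j])
    # local sub-grid refinement around the coarse minimum
    fine = grid_step_mm / 5.0
    gf = np.arange(-grid_step_mm, grid_step_mm + fine / 2, fine)
    fx, fy = np.meshgrid(x0 + gf, y0 + gf)
    fs = rbf(np.column_stack([fx.ravel(), fy.ravel()])).reshape(fx.shape)
    i, j = np.unravel_index(np.argmin(fs), fs.shape)
    x0, y0 = float(fx[i, j]), float(fy[i, j])
    if np.hypot(x0, y0) > 0.6:
        warnings.warn("foveal estimate outside the central 2 degrees", UnreliableCenterWarning)
    return x0, y0


def resample_radial(
    samples: ThicknessSamples,
    center: Tuple[float, float],
    n_angles: int = 6,
    angular_step: float = 30.0,
    r_max_mm: float = 2.25,
    n_radial: int = 840,
) -> ThicknessSamples:
    """Reinterpolate scattered thickness samples onto a recentered radial grid."""
    interp = LinearNDInterpolator(
        np.column_stack([samples.x_mm, samples.y_mm]), samples.value_um
    )
    s = np.linspace(-r_max_mm, r_max_mm, n_radial)
    xs, ys = [], []
    for k in range(n_angles):
        th = np.deg2rad(k * angular_step)
        xs.append(center[0] + s * np.cos(th))
        ys.append(center[1] + s * np.sin(th))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    v = interp(np.column_stack([x, y]))
    ok = np.isfinite(v)
    return ThicknessSamples(
        x[ok] - center[0], y[ok] - center[1], v[ok], ds_mm=float(s[1] - s[0]), label=samples.label
    )


def eccentricity_proxy(
    boundaries: BoundarySet,
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    ds_mm: float,
    angle_deg: Optional[float] = None,
) -> ThicknessSamples:
    """Inner band 2 → outer band 4 thickness: an anatomical eccentricity proxy.

    This combined outer-segment + RPE + BM thickness peaks at the fovea
    and declines with eccentricity, so large values mean central retina
    without requiring any centration.
    """
    return layer_thickness(boundaries, "EZ_inner", "BM_outer", x_mm, y_mm, ds_mm, angle_deg)


def sector_average(samples: ThicknessSamples, grid: Optional[SectorGrid] = None) -> SectorStats:
    """Area-weighted sector means over the 9-region macular grid.

    Each radial sample is weighted by the annulus area it represents
    (∝ |r|·Δr); weights are normalized within each region.
    """
    grid = grid or SectorGrid()
    labels = grid.assign(samples.x_mm, samples.y_mm)
    w = samples.area_weights()
    means: Dict[str, float] = {}
    for region in grid.region_names:
        m = labels == region
        if not np.any(m):
            raise MissingCoverageError(f"no samples in region {region}", region=region)
        means[region] = float(np.average(samples.value_um[m], weights=w[m]))
    return SectorStats(region_means=means, grid=grid)


def cohort_sector_stats(per_eye: Sequence[SectorStats]) -> pd.DataFrame:
    """Across-eye mean, SD and CoV per region (plus ring aggregates)."""
    if len(per_eye) == 0:
        raise EmptyInputError("no eyes")
    rows = []
    regions = per_eye[0].grid.region_names
    for region in regions:
        vals = np.array([s.region_means[region] for s in per_eye])
        rows.append((region, vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0, len(vals)))
    for ring in ("central_disc", "inner_annulus", "outer_annulus"):
        vals = np.array([s.ring_means()[ring] for s in per_eye])
        rows.append((ring, vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0, len(vals)))
    df = pd.DataFrame(rows, columns=["region", "mean_um", "sd_um", "n"])
    df["cov"] = df["sd_um"] / df["mean_um"]
    return df


@dataclass
class ProportionalFit:
    """Linear regression through the origin: y = slope * x."""

    slope: float
    ci95: Tuple[float, float]
    n: int


def proportional_fit(x: np.ndarray, y: np.ndarray) -> ProportionalFit:
    """Through-origin least squares: slope = Σxy/Σx² with a normal-theory CI."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 2:
        raise InvalidInputError("need n >= 2 paired samples")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise DegenerateFitError("all x are zero")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return ProportionalFit(slope=slope, ci95=(slope - 1.96 * se, slope + 1.96 * se), n=x.size)


def thickness_histogram2d(
    proxy: ThicknessSamples,
    thickness: ThicknessSamples,
    bins: Tuple[int, int] = (30, 30),
):
    """Joint histogram of (proxy, thickness) plus per-proxy-bin mean ± SD.

    Returns ``(counts, proxy_edges, thickness_edges, per_bin)`` where
    ``per_bin`` is a frame with bin centers, mean and SD thickness and
    counts per proxy bin.
    """
    x = proxy.value_um
    y = thickness.value_um
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("empty samples")
    if x.size != y.size:
        raise InvalidInputError("proxy and thickness must be paired")
    counts, xe, ye, _ = binned_statistic_2d(x, y, None, statistic="count", bins=bins)
    mean, edges, _ = binned_statistic(x, y, statistic="mean", bins=bins[0])
    sd, _, _ = binned_statistic(x, y, statistic="std", bins=edges)
    cnt, _, _ = binned_statistic(x, y, statistic="count", bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_bin = pd.DataFrame(
        {"proxy_um": centers, "mean_um": mean, "sd_um": sd, "n": cnt.astype(int)}
    )
    return counts, xe, ye, per_bin
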