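"""Depth-resolved RPE interior reflectivity by eccentricity.

The RPE interior is sampled per A-scan on a percentage-depth grid
between the apical RPE boundary (0 %) and the inner BM boundary
(100 %), averaged within eccentricity bins, and normalized so every
bin's intensity at 0 % depth equals 1.  Converting percentage depth to
absolute depth (via each bin's mean RPE thickness) separates two
explanations of a stronger foveal intensity drop: a higher *areal*
density of attenuators versus a thicker RPE at constant *volumetric*
density — the latter predicts equal log-decay rates per µm across
eccentricities, which :func:`log_decay_rate` measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import (
    EmptyInputError,
    InvalidDomainError,
    InvalidInputError,
    MissingMetadataError,
)
from .segmentation import BoundarySet

__all__ = [
    "DEFAULT_ECC_BINS",
    "RPEIntensityProfile",
    "internal_intensity_profile",
    "combine_profiles",
    "to_absolute_depth",
    "log_decay_rate",
]

#: default eccentricity bins (mm)
DEFAULT_ECC_BINS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.5),
    (0.5, 1.0),
    (1.0, 1.5),
    (1.5, 2.25),
    (2.25, 3.0),
    (3.0, 4.5),
)


@dataclass
class RPEIntensityProfile:
    """Normalized RPE interior intensity vs percentage depth per bin."""

    pct_depth_grid: np.ndarray  # 0..100
    normalized_intensity: np.ndarray  # (n_bins, n_pct); NaN rows = excluded bins
    eccentricity_bins: Tuple[Tuple[float, float], ...]
    mean_rpe_thickness: np.ndarray  # µm per bin
    n_columns: np.ndarray  # columns contributing per bin

    def bin_ok(self) -> np.ndarray:
        return ~np.isnan(self.normalized_intensity).all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, (lo, hi) in enumerate(self.eccentricity_bins):
            for pi, p in enumerate(self.pct_depth_grid):
                rows.append((f"{lo}-{hi}", p, self.normalized_intensity[bi, pi],
                             self.mean_rpe_thickness[bi], int(self.n_columns[bi])))
        return pd.DataFrame(rows, columns=["bin_mm", "pct_depth", "intensity", "mean_thickness_um", "n"])


def internal_intensity_profile(
    bscan: np.ndarray,
    boundaries: BoundarySet,
    eccentricity_mm: np.ndarray,
    bins: Sequence[Tuple[float, float]] = DEFAULT_ECC_BINS,
    pct_step: float = 2.0,
    min_columns: int = 50,
) -> RPEIntensityProfile:
    """Percentage-depth RPE intensity profile of one B-scan.

    Each column is resampled by linear interpolation on the 0-100 %
    grid between ``RPE_apical`` and ``BM_inner``, averaged within each
    |eccentricity| bin, and normalized to 1 at 0 % depth.  Bins with
    fewer than ``min_columns`` columns are excluded (NaN rows).
    """
    img = np.asarray(bscan, float)
    top = boundaries["RPE_apical"]
    bot = boundaries["BM_inner"]
    ok = (~boundaries.mask) & (bot > top)
    pct = np.arange(0.0, 100.0 + pct_step / 2, pct_step)
    rows = top[None, :] + (pct[:, None] / 100.0) * (bot - top)[None, :]
    cols = np.broadcast_to(np.arange(img.shape[1])[None, :], rows.shape)
    sampled = map_coordinates(img, [rows, cols], order=1, mode="nearest")  # (n_pct, n_cols)

    ecc = np.abs(np.asarray(eccentricity_mm, float))
    n_bins = len(bins)
    out = np.full((n_bins, pct.size), np.nan)
    thick = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for bi, (lo, hi) in enumerate(bins):
        m = ok & (ecc >= lo) & (ecc < hi)
        counts[bi] = int(m.sum())
        if counts[bi] < min_columns:
            continue
        prof = sampled[:, m].mean(axis=1)
        if prof[0] <= 0:
            continue
        out[bi] = prof / prof[0]
        thick[bi] = float(((bot - top)[m] * boundaries.axial_pixel_um).mean())
    if not np.any(~np.isnan(out)):
        raise EmptyInputError("no eccentricity bin met the minimum column count")
    return RPEIntensityProfile(
        pct_depth_grid=pct,
        normalized_intensity=out,
        eccentricity_bins=tuple(tuple(b) for b in bins),
        mean_rpe_thickness=thick,
        n_columns=counts,
    )


def combine_profiles(profiles: Sequence[RPEIntensityProfile]) -> RPEIntensityProfile:
    """Unweighted across-scan/subject mean of per-bin normalized profiles."""
    if len(profiles) == 0:
        raise EmptyInputError("no profiles")
    ref = profiles[0]
    stack = np.stack([p.normalized_intensity for p in profiles])
    thick = np.stack([p.mean_rpe_thickness for p in profiles])
    counts = np.stack([p.n_columns for p in profiles])
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)  # all-NaN bins stay NaN (excluded)
        mthick = np.nanmean(thick, axis=0)
    return RPEIntensityProfile(
        pct_depth_grid=ref.pct_depth_grid,
        normalized_intensity=mean,
        eccentricity_bins=ref.eccentricity_bins,
        mean_rpe_thickness=mthick,
        n_columns=counts.sum(axis=0),
    )


def to_absolute_depth(
    profile: RPEIntensityProfile,
    depth_step_um: float = 0.25,
) -> Dict[Tuple[float, float], Tuple[np.ndarray, np.ndarray]]:
    """Per-bin intensity versus absolute depth (µm).

    Maps each bin's percentage grid to micrometres via its mean RPE
    thickness and resamples onto a common uniform depth grid; each
    curve ends at its bin's mean thickness.
    """
    out = {}
    for bi, bin_ in enumerate(profile.eccentricity_bins):
        t = profile.mean_rpe_thickness[bi]
        y = profile.normalized_intensity[bi]
        if np.isnan(t) or np.all(np.isnan(y)):
            continue
        if not np.isfinite(t):
            raise MissingMetadataError(f"no mean thickness for bin {bin_}")
        depth_native = profile.pct_depth_grid / 100.0 * t
        grid = np.arange(0.0, t + depth_step_um / 2, depth_step_um)
        out[bin_] = (grid, np.interp(grid, depth_native, y))
    if not out:
        raise MissingMetadataError("no bin has both a profile and a mean thickness")
    return out


def log_decay_rate(
    depth_um: np.ndarray,
    intensity: np.ndarray,
    depth_range: Tuple[float, float],
) -> float:
    """Exponential decay rate (1/µm) of an intensity-depth curve.

    Least-squares slope of ln(intensity) over ``depth_range``, sign
    flipped so a decaying curve gives a positive rate.
    """
    z = np.asarray(depth_um, float)
    y = np.asarray(intensity, float)
    m = (z >= depth_range[0]) & (z <= depth_range[1])
    if m.sum() < 2:
        raise InvalidInputError("depth_range holds fewer than 2 samples")
    if np.any(y[m] <= 0):
        raise InvalidDomainError("intensity must be strictly positive on the range")
    slope = np.polyfit(z[m], np.log(y[m]), 1)[0]
    return float(-slope)
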