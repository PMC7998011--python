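"""Depth-resolved linear-intensity profiles on a uniform axial grid.

The :class:`DepthProfile` is the common currency between the Monte Carlo
simulator, the synthetic renderer and the Bruch's-membrane quantification:
a single A-scan (or transverse average of aligned A-scans) sampled on a
uniform depth grid in micrometres.  By convention the Bruch's membrane
reference plane sits at ``z = 0`` with the RPE at negative depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["DepthProfile"]


@dataclass
class DepthProfile:
    """A depth-resolved linear-intensity profile.

    Parameters
    ----------
    z : ndarray
        Strictly increasing, uniformly spaced depths in µm.
    intensity : ndarray
        Non-negative linear intensity per depth sample.
    n_photons : int, optional
        Number of photon packets launched (Monte Carlo provenance).
    seed : int, optional
        Seed of the random stream that produced the profile.
    path_class_split : mapping, optional
        Per-class profiles (``ballistic``, ``quasi_ballistic``,
        ``multiple``) that sum to ``intensity``.
    """

    z: np.ndarray
    intensity: np.ndarray
    n_photons: Optional[int] = None
    seed: Optional[int] = None
    path_class_split: Optional[Mapping[str, np.ndarray]] = field(default=None)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.intensity.shape:
            raise InvalidInputError("z and intensity must be 1-D and equal length")
        if self.z.size < 2:
            raise InvalidInputError("profile needs at least two samples")
        dz = np.diff(self.z)
        if np.any(dz <= 0):
            raise InvalidInputError("z must be strictly increasing")
        if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
            raise InvalidInputError("z must be uniformly spaced")
        if np.any(self.intensity < -1e-12 * max(1.0, float(np.max(np.abs(self.intensity))))):
            raise InvalidInputError("intensity must be non-negative")
        if self.path_class_split is not None:
            total = sum(np.asarray(v, float) for v in self.path_class_split.values())
            if not np.allclose(total, self.intensity, rtol=1e-6, atol=1e-9 * max(1.0, float(self.intensity.max()))):
                raise InvalidInputError("path-class profiles must sum to the total")

    @property
    def spacing(self) -> float:
        """Grid spacing in µm."""
        return float(self.z[1] - self.z[0])

    def interp(self, z: np.ndarray) -> np.ndarray:
        """Linear interpolation of the intensity at arbitrary depths."""
        return np.interp(np.asarray(z, float), self.z, self.intensity)

    def window(self, lo: float, hi: float) -> "DepthProfile":
        """Sub-profile restricted to ``lo <= z <= hi`` (µm)."""
        m = (self.z >= lo) & (self.z <= hi)
        if m.sum() < 2:
            raise InvalidInputError(f"window [{lo}, {hi}] contains <2 samples")
        return DepthProfile(self.z[m], self.intensity[m], self.n_photons, self.seed)

    def to_csv(self, path) -> None:
        """Write as two-column CSV (depth_um, intensity)."""
        pd.DataFrame({"depth_um": self.z, "intensity": self.intensity}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DepthProfile":
        df = pd.read_csv(path)
        return cls(df["depth_um"].to_numpy(), df["intensity"].to_numpy())
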