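"""Continuous lesion geometries for point-pattern analysis.

Radial density profiles and boundary distances need a signed distance for
arbitrary (x, y) positions, not just spot centroids. Two geometries are
provided: an analytic one for planted disk lesions (exact distances and
annulus areas) and a lattice-interpolated one for lesions detected from
expression (nearest-spot distance, tile-count areas).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidConfigurationError
from .lattice import SpotLattice


@dataclasses.dataclass(frozen=True)
class DiskGeometry:
    """Union of disk lesions: centers (k, 2) and radii (k,), in um.

    Signed distance of a point is ``min_k(||p - c_k|| - r_k)`` — negative
    inside a disk, positive outside. Band areas assume the distance bands of
    different lesions do not overlap (guaranteed by the simulator's minimum
    separation constraint).
    """

    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if centers.shape[0] != radii.shape[0] or (centers.shape[0] and centers.shape[1] != 2):
            raise InvalidConfigurationError("centers must be (k, 2) and radii (k,)")
        if np.any(radii <= 0):
            raise InvalidConfigurationError("lesion radii must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)

    @property
    def n_lesions(self) -> int:
        return self.centers.shape[0]

    def signed_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Signed distance and nearest lesion id for (n, 2) point array."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_lesions == 0:
            return np.full(len(pts), np.inf), np.full(len(pts), -1, dtype=int)
        diff = pts[:, None, :] - self.centers[None, :, :]
        d_all = np.linalg.norm(diff, axis=2) - self.radii[None, :]
        nearest = np.argmin(d_all, axis=1)  # first occurrence = smallest id
        return d_all[np.arange(len(pts)), nearest], nearest.astype(int)

    def band_area_um2(self, lo: float, hi: float) -> float:
        """Area of the signed-distance band (lo, hi], summed over lesions."""
        if hi <= lo:
            raise InvalidConfigurationError("band requires hi > lo")
        r_out = np.maximum(self.radii + hi, 0.0)
        r_in = np.maximum(self.radii + lo, 0.0)
        return float(np.pi * np.sum(r_out**2 - r_in**2))


@dataclasses.dataclass(frozen=True)
class LatticeGeometry:
    """Signed distance field carried on a spot lattice.

    Points inherit the signed distance of their nearest spot; band areas are
    tile counts times the tile area. ``field`` is the DataFrame produced by
    :func:`rizmap.lattice.signed_distance`.
    """

    lattice: SpotLattice
    field: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.field.index.equals(self.lattice.spot_ids):
            raise InvalidConfigurationError(
                "field index must match the lattice spot ids"
            )

    def signed_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tree = cKDTree(self.lattice.coords())
        _, idx = tree.query(pts)
        d = self.field["d_um"].to_numpy()[idx]
        lesion = self.field["nearest_lesion_id"].to_numpy()[idx]
        return d, lesion.astype(int)

    def band_area_um2(self, lo: float, hi: float) -> float:
        if hi <= lo:
            raise InvalidConfigurationError("band requires hi > lo")
        d = self.field["d_um"].to_numpy()
        n = int(np.sum((d > lo) & (d <= hi)))
        return n * self.lattice.tile_area_um2
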