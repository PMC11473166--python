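"""Spot-lattice geometry.

The capture units of array-based spatial transcriptomics sit on a regular
lattice: Visium uses a hexagonal arrangement with ~100 um center-to-center
spacing; enhanced-resolution subspot tables are treated as ordinary spots.
This module provides the lattice container, its adjacency graph, connected
components and the signed Euclidean distance to a lesion-core boundary
(negative inside the core, positive outside, boundary at 0).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _csgraph_cc
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, InvalidConfigurationError

#: Row pitch of the regular triangular (hex) lattice, as a fraction of spacing.
HEX_ROW_PITCH = math.sqrt(3.0) / 2.0

LATTICE_KINDS = ("hex", "square")


@dataclasses.dataclass(frozen=True)
class SpotLattice:
    """Spot identities with um centroids on a hex or square lattice.

    Attributes
    ----------
    spots
        DataFrame indexed by unique ``spot_id`` with columns ``x_um``,
        ``y_um``, ``array_row``, ``array_col``, ``in_tissue``.
    lattice_kind
        ``"hex"`` or ``"square"``.
    spacing_um
        Center-to-center spacing between nearest neighbors, in um.
    """

    spots: pd.DataFrame
    lattice_kind: str
    spacing_um: float

    def __post_init__(self) -> None:
        if self.lattice_kind not in LATTICE_KINDS:
            raise InvalidConfigurationError(
                f"lattice_kind must be one of {LATTICE_KINDS}, got {self.lattice_kind!r}"
            )
        if not (self.spacing_um > 0):
            raise InvalidConfigurationError("spacing_um must be positive")
        if self.spots.index.has_duplicates:
            raise InvalidConfigurationError("spot_id values must be unique")
        coords = self.spots[["x_um", "y_um"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise InvalidConfigurationError("spot coordinates must be finite")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def spot_ids(self) -> pd.Index:
        return self.spots.index

    def coords(self) -> np.ndarray:
        """(n, 2) array of ``x_um, y_um`` centroids in spot order."""
        return self.spots[["x_um", "y_um"]].to_numpy(float)

    @property
    def tile_area_um2(self) -> float:
        """Area attributed to one spot: (sqrt(3)/2) s^2 on hex, s^2 on square."""
        s2 = self.spacing_um**2
        return HEX_ROW_PITCH * s2 if self.lattice_kind == "hex" else s2

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the spot centroids, in um."""
        xy = self.coords()
        return (
            float(xy[:, 0].min()),
            float(xy[:, 1].min()),
            float(xy[:, 0].max()),
            float(xy[:, 1].max()),
        )

    def neighbor_radius_um(self) -> float:
        """Adjacency cutoff: 1.05 s (hex, 6-neighbor) or 1.5 s (square, queen)."""
        factor = 1.05 if self.lattice_kind == "hex" else 1.5
        return factor * self.spacing_um


def generate_lattice(
    n_rows: int,
    n_cols: int,
    lattice_kind: str = "hex",
    spacing_um: float = 100.0,
) -> SpotLattice:
    """Generate a regular spot lattice.

    Square lattices place spots on an ``n_rows x n_cols`` grid with pitch
    ``spacing_um`` in both directions. Hex lattices offset odd rows by half a
    spacing and use row pitch ``spacing_um * sqrt(3)/2`` (a regular triangular
    lattice), so every interior spot has six neighbors at exactly
    ``spacing_um``.
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidConfigurationError("n_rows and n_cols must be >= 1")
    if not (spacing_um > 0):
        raise InvalidConfigurationError("spacing_um must be positive")
    if lattice_kind not in LATTICE_KINDS:
        raise InvalidConfigurationError(
            f"lattice_kind must be one of {LATTICE_KINDS}, got {lattice_kind!r}"
        )
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows = rows.ravel()
    cols = cols.ravel()
    if lattice_kind == "hex":
        x = cols * spacing_um + (rows % 2) * (spacing_um / 2.0)
        y = rows * spacing_um * HEX_ROW_PITCH
    else:
        x = cols * spacing_um
        y = rows * spacing_um
    ids = [f"s{r:04d}_{c:04d}" for r, c in zip(rows, cols)]
    spots = pd.DataFrame(
        {
            "x_um": x.astype(float),
            "y_um": y.astype(float),
            "array_row": rows.astype(int),
            "array_col": cols.astype(int),
            "in_tissue": True,
        },
        index=pd.Index(ids, name="spot_id"),
    )
    return SpotLattice(spots, lattice_kind, float(spacing_um))


def build_adjacency(lattice: SpotLattice) -> sparse.csr_matrix:
    """Neighbor graph of the lattice.

    Returns a symmetric CSR matrix (spot order = lattice order) whose entries
    are Euclidean centroid distances; pairs further apart than the lattice's
    neighbor radius are absent. No self-edges.
    """
    coords = lattice.coords()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=lattice.neighbor_radius_um(), output_type="ndarray")
    n = lattice.n_spots
    if len(pairs) == 0:
        return sparse.csr_matrix((n, n))
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    w = np.concatenate([d, d])
    return sparse.csr_matrix((w, (i, j)), shape=(n, n))


def connected_components(
    lattice: SpotLattice,
    subset: Iterable[str],
    adjacency: sparse.csr_matrix | None = None,
) -> list[list[str]]:
    """Partition ``subset`` into maximal connected groups under adjacency.

    Components are ordered by (size descending, smallest spot_id); spot ids
    within each component are sorted. An empty subset yields an empty list.
    """
    subset_ids = pd.Index(subset)
    if len(subset_ids) == 0:
        return []
    missing = subset_ids.difference(lattice.spot_ids)
    if len(missing) > 0:
        raise InvalidConfigurationError(
            f"subset contains {len(missing)} spot ids not in the lattice, "
            f"e.g. {missing[0]!r}"
        )
    if adjacency is None:
        adjacency = build_adjacency(lattice)
    pos = lattice.spot_ids.get_indexer(subset_ids)
    sub = adjacency[pos][:, pos]
    n_comp, labels = _csgraph_cc(sub, directed=False)
    groups: dict[int, list[str]] = {}
    for spot_id, lab in zip(subset_ids, labels):
        groups.setdefault(int(lab), []).append(spot_id)
    comps = [sorted(g) for g in groups.values()]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def signed_distance(
    lattice: SpotLattice,
    core: Iterable[str],
    adjacency: sparse.csr_matrix | None = None,
) -> pd.DataFrame:
    """Signed Euclidean distance of every spot to the lesion-core boundary.

    For a non-core spot, ``d_um`` is +(min distance to any core-spot
    centroid); for a core spot, -(min distance to any non-core-spot
    centroid). ``nearest_lesion_id`` is the connected core component owning
    the minimizing core spot (outside) or the spot's own component (inside);
    exact distance ties are broken toward the smallest lesion id.

    Returns a DataFrame indexed like the lattice with columns ``d_um`` and
    ``nearest_lesion_id``. Raises :class:`DegenerateGeometryError` when the
    core covers every spot (no boundary exists) and
    :class:`InvalidConfigurationError` when the core is empty.
    """
    core_ids = pd.Index(core)
    if len(core_ids) == 0:
        raise InvalidConfigurationError("core spot set must be non-empty")
    missing = core_ids.difference(lattice.spot_ids)
    if len(missing) > 0:
        raise InvalidConfigurationError(
            f"core contains {len(missing)} spot ids not in the lattice"
        )
    is_core = lattice.spot_ids.isin(core_ids)
    if is_core.all():
        raise DegenerateGeometryError(
            "core set covers all spots: the lesion boundary is undefined"
        )

    comps = connected_components(lattice, core_ids, adjacency=adjacency)
    lesion_of_spot: dict[str, int] = {}
    for lesion_id, comp in enumerate(comps):
        for sid in comp:
            lesion_of_spot[sid] = lesion_id

    coords = lattice.coords()
    core_xy = coords[is_core]
    out_xy = coords[~is_core]
    core_lesion = np.array(
        [lesion_of_spot[sid] for sid in lattice.spot_ids[is_core]], dtype=int
    )

    d = np.empty(lattice.n_spots, dtype=float)
    nearest = np.empty(lattice.n_spots, dtype=int)

    # Outside spots: nearest core centroid; ties -> smallest lesion id.
    D_out = cdist(out_xy, core_xy)
    dmin = D_out.min(axis=1)
    tie = D_out <= (dmin[:, None] + 1e-9)
    lesion_grid = np.where(tie, core_lesion[None, :], np.iinfo(np.int64).max)
    d[~is_core] = dmin
    nearest[~is_core] = lesion_grid.min(axis=1)

    # Core spots: negative distance to nearest non-core centroid.
    D_in = cdist(core_xy, out_xy)
    d[is_core] = -D_in.min(axis=1)
    nearest[is_core] = core_lesion

    return pd.DataFrame(
        {"d_um": d, "nearest_lesion_id": nearest}, index=lattice.spot_ids
    )


def edge_flags(lattice: SpotLattice, margin_um: float) -> pd.Series:
    """Boolean flag per spot: within ``margin_um`` of the lattice bounding box.

    Zones clipped by the tissue edge have truncated annuli; callers may
    exclude flagged spots from agreement denominators.
    """
    xmin, ymin, xmax, ymax = lattice.bounding_box
    xy = lattice.coords()
    flag = (
        (xy[:, 0] - xmin < margin_um)
        | (xmax - xy[:, 0] < margin_um)
        | (xy[:, 1] - ymin < margin_um)
        | (ymax - xy[:, 1] < margin_um)
    )
    return pd.Series(flag, index=lattice.spot_ids, name="edge")
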