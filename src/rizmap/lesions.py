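"""Lesion-core detection and the expected concentric zone model.

Necrotic/inflammatory lesion cores are detected as connected components of
spots whose zone-A (damage-clearing) module score exceeds a high quantile of
its distribution; components smaller than ``min_core_spots`` are discarded.
The expected zone model then follows from the signed distance to the core
boundary: zone A inside the core (d <= 0), zone B in the barrier annulus
(0 < d <= w_B, default 100 um), zone C in the regenerating periphery
(w_B < d <= w_C, default 440 um), and ``none`` beyond.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import InvalidConfigurationError
from .lattice import (
    SpotLattice,
    build_adjacency,
    connected_components,
    edge_flags,
    signed_distance,
)
from .simulate import _zone_from_distance

logger = logging.getLogger(__name__)

DEFAULT_W_B_UM = 100.0
DEFAULT_W_C_UM = 440.0


@dataclasses.dataclass(frozen=True)
class Lesion:
    """One detected lesion core."""

    lesion_id: int
    core_spots: tuple[str, ...]
    boundary_spots: tuple[str, ...]  # core spots adjacent to >= 1 non-core spot
    area_mm2: float

    @property
    def n_core_spots(self) -> int:
        return len(self.core_spots)


@dataclasses.dataclass(frozen=True)
class LesionSet:
    """Detected lesions, ordered by (size desc, smallest spot id)."""

    lesions: tuple[Lesion, ...]

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def core_union(self) -> list[str]:
        return [sid for les in self.lesions for sid in les.core_spots]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lesion_id": [l.lesion_id for l in self.lesions],
                "n_core_spots": [l.n_core_spots for l in self.lesions],
                "n_boundary_spots": [len(l.boundary_spots) for l in self.lesions],
                "area_mm2": [l.area_mm2 for l in self.lesions],
            }
        ).set_index("lesion_id")


def lesions_from_spots(
    lattice: SpotLattice,
    core_spots: list[str],
    min_core_spots: int = 1,
    adjacency: sparse.csr_matrix | None = None,
) -> LesionSet:
    """Build a :class:`LesionSet` from an explicit core spot list.

    Used both by :func:`detect_cores` and to reproduce annotation-driven
    analyses from a user-supplied core spot file.
    """
    if adjacency is None:
        adjacency = build_adjacency(lattice)
    comps = connected_components(lattice, core_spots, adjacency=adjacency)
    comps = [c for c in comps if len(c) >= min_core_spots]
    tile_mm2 = lattice.tile_area_um2 / 1e6
    in_core = set(sid for c in comps for sid in c)
    pos_of = {sid: i for i, sid in enumerate(lattice.spot_ids)}
    lesions = []
    for lesion_id, comp in enumerate(comps):
        boundary = []
        for sid in comp:
            row = adjacency[pos_of[sid]]
            nbrs = lattice.spot_ids[row.indices]
            if any(n not in in_core for n in nbrs) or len(nbrs) == 0:
                boundary.append(sid)
        lesions.append(
            Lesion(
                lesion_id=lesion_id,
                core_spots=tuple(comp),
                boundary_spots=tuple(sorted(boundary)),
                area_mm2=len(comp) * tile_mm2,
            )
        )
    return LesionSet(tuple(lesions))


def detect_cores(
    lattice: SpotLattice,
    zone_a_scores: pd.Series,
    threshold_quantile: float = 0.90,
    min_core_spots: int = 5,
    adjacency: sparse.csr_matrix | None = None,
) -> LesionSet:
    """Detect lesion cores from zone-A module scores.

    Candidate spots score strictly above the ``threshold_quantile`` quantile;
    connected components under lattice adjacency with at least
    ``min_core_spots`` spots become lesions. The rule depends on score ranks
    only, so it is invariant to any strictly monotone transform of the score
    vector. An empty result is returned (and logged), not raised.
    """
    if not (0 < threshold_quantile < 1):
        raise InvalidConfigurationError("threshold_quantile must be in (0, 1)")
    if min_core_spots < 1:
        raise InvalidConfigurationError("min_core_spots must be >= 1")
    scores = zone_a_scores.reindex(lattice.spot_ids)
    if scores.isna().any():
        raise InvalidConfigurationError("zone-A scores missing for some lattice spots")
    thr = float(np.quantile(scores.to_numpy(float), threshold_quantile))
    candidates = scores.index[scores.to_numpy(float) > thr].tolist()
    lesion_set = lesions_from_spots(
        lattice, candidates, min_core_spots=min_core_spots, adjacency=adjacency
    )
    if len(lesion_set) == 0:
        logger.info(
            "no lesion core survived (quantile %.2f, min_core_spots %d)",
            threshold_quantile,
            min_core_spots,
        )
    return lesion_set


@dataclasses.dataclass(frozen=True)
class ExpectedZoneMap:
    """Per-spot expected zones derived from a signed-distance field.

    ``frame`` is indexed by spot id with columns ``expected_zone``, ``d_um``,
    ``nearest_lesion_id`` and ``edge`` (spot within ``w_C`` of the lattice
    bounding box, where annuli may be clipped).
    """

    frame: pd.DataFrame
    w_B_um: float
    w_C_um: float

    @property
    def zones(self) -> pd.Series:
        return self.frame["expected_zone"]


def expected_zones(
    field: pd.DataFrame,
    w_B_um: float = DEFAULT_W_B_UM,
    w_C_um: float = DEFAULT_W_C_UM,
    lattice: SpotLattice | None = None,
) -> ExpectedZoneMap:
    """Expected zone per spot from a signed-distance field.

    ``field`` is the DataFrame returned by
    :func:`rizmap.lattice.signed_distance` (columns ``d_um``,
    ``nearest_lesion_id``). Intervals are half-open on the outer edge:
    A iff d <= 0; B iff 0 < d <= w_B; C iff w_B < d <= w_C; none beyond.
    When a lattice is supplied, spots within ``w_C`` of its bounding box are
    flagged ``edge=True``.
    """
    if not (0 < w_B_um < w_C_um):
        raise InvalidConfigurationError("require 0 < w_B_um < w_C_um")
    d = field["d_um"].to_numpy(float)
    zone = _zone_from_distance(d, w_B_um, w_C_um)
    frame = pd.DataFrame(
        {
            "expected_zone": zone,
            "d_um": d,
            "nearest_lesion_id": field["nearest_lesion_id"].to_numpy(int),
        },
        index=field.index,
    )
    if lattice is not None:
        frame["edge"] = edge_flags(lattice, w_C_um).reindex(frame.index).to_numpy()
    else:
        frame["edge"] = False
    return ExpectedZoneMap(frame, float(w_B_um), float(w_C_um))


def expected_zones_from_lesions(
    lattice: SpotLattice,
    lesion_set: LesionSet,
    w_B_um: float = DEFAULT_W_B_UM,
    w_C_um: float = DEFAULT_W_C_UM,
    adjacency: sparse.csr_matrix | None = None,
) -> tuple[ExpectedZoneMap, pd.DataFrame]:
    """Convenience: signed distance from detected cores, then expected zones.

    Returns the zone map and the signed-distance field.
    """
    field = signed_distance(lattice, lesion_set.core_union(), adjacency=adjacency)
    return expected_zones(field, w_B_um, w_C_um, lattice=lattice), field
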