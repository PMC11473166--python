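"""Spatial organization statistics.

Three families of read-outs quantify how organized (or collapsed) the zone
architecture is:

* pairwise Spearman correlation of zone markers across spots — organized
  tissue shows near-zero or negative cross-zone correlation (disjoint
  territories), collapsed tissue shows elevated cross-zone correlation;
* boundary-referenced radial profiles of labeled cell points — densities per
  signed-distance bin around the lesion boundary, and mean boundary
  distances;
* a nearest-neighbor proximity fraction with a relabeling permutation null —
  e.g. the fraction of one macrophage class lying within 20 um of
  regenerating fibers, against a competing class.
"""

from __future__ import annotations

import dataclasses
import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .errors import InvalidConfigurationError
from .panel import ZonePanel, match_genes
from .scoring import _norm_matrix

logger = logging.getLogger(__name__)

#: Default signed-distance bin edges (um): 50-um steps from -100 (inside the
#: necrotic boundary) to +450 (outside), half-open (lo, hi].
DEFAULT_BIN_EDGES = tuple(float(e) for e in range(-100, 451, 50))


# ---------------------------------------------------------------------------
# Marker correlation


@dataclasses.dataclass(frozen=True)
class CorrelationReport:
    """Marker x marker Spearman matrix and its cross-zone summary."""

    matrix: pd.DataFrame
    gene_zones: pd.Series
    mean_cross_zone: float
    n_spots: int

    def to_dict(self) -> dict:
        return {
            "mean_cross_zone": self.mean_cross_zone,
            "n_spots": self.n_spots,
            "genes": list(self.matrix.index),
            "gene_zones": self.gene_zones.to_dict(),
        }


def _spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Spearman matrix over columns of X (spots x genes), ties mid-ranked.

    Constant columns yield NaN off-diagonal entries; the diagonal is 1.
    """
    ranks = rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return r


def _cross_zone_mean(r: np.ndarray, zones: np.ndarray) -> float:
    cross = zones[:, None] != zones[None, :]
    vals = r[cross]
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def marker_correlation(
    adata: ad.AnnData,
    panel: ZonePanel,
    spot_subset: pd.Index | list[str] | None = None,
    case_insensitive: bool = False,
) -> CorrelationReport:
    """Pairwise Spearman correlation of panel markers over spots.

    ``spot_subset`` restricts the spot universe (e.g. to lesion-proximal
    foci); by default all spots are used. At least 3 spots are required.
    Genes constant over the subset get NaN correlations with a logged
    warning. The cross-zone summary is the mean of entries whose two genes
    belong to different zones.
    """
    if spot_subset is not None:
        adata = adata[pd.Index(spot_subset)]
    if adata.n_obs < 3:
        raise InvalidConfigurationError("need at least 3 spots for correlation")
    X = _norm_matrix(adata)
    zone_of = panel.zone_of()
    genes = match_genes(panel.genes, list(adata.var_names), case_insensitive)
    if len(genes) < 2:
        raise InvalidConfigurationError("need at least 2 panel genes in the matrix")
    cols = [list(adata.var_names).index(g) for g in genes]
    Xg = X[:, cols]
    const = Xg.std(axis=0) == 0
    if const.any():
        logger.warning(
            "%d panel genes constant over the subset; correlations reported missing: %s",
            int(const.sum()),
            [g for g, c in zip(genes, const) if c],
        )
    r = _spearman_matrix(Xg)
    zones = np.array([zone_of[g] for g in genes], dtype=object)
    return CorrelationReport(
        matrix=pd.DataFrame(r, index=genes, columns=genes),
        gene_zones=pd.Series(zones, index=genes, name="zone"),
        mean_cross_zone=_cross_zone_mean(r, zones),
        n_spots=adata.n_obs,
    )


@dataclasses.dataclass(frozen=True)
class CollapseCorrelationResult:
    """Cross-zone correlation difference (disrupted - organized) and its null."""

    statistic: float
    p_value: float
    mean_cross_zone_organized: float
    mean_cross_zone_disrupted: float
    null: np.ndarray
    n_perm: int


def collapse_correlation_test(
    adata_organized: ad.AnnData,
    adata_disrupted: ad.AnnData,
    panel: ZonePanel,
    n_perm: int = 1000,
    seed: int = 0,
) -> CollapseCorrelationResult:
    """Is cross-zone marker correlation higher in the disrupted condition?

    The statistic is mean cross-zone Spearman correlation (disrupted) minus
    (organized). The null permutes condition labels over the pooled spots,
    holding each gene's expression fixed, and recomputes both means; the
    one-sided p-value is ``(1 + #{null >= stat}) / (n_perm + 1)``.
    """
    genes = match_genes(panel.genes, list(adata_organized.var_names))
    genes_d = match_genes(panel.genes, list(adata_disrupted.var_names))
    if genes != genes_d:
        raise InvalidConfigurationError(
            "the two datasets must share the same panel genes"
        )
    zone_of = panel.zone_of()
    zones = np.array([zone_of[g] for g in genes], dtype=object)

    def extract(adata: ad.AnnData) -> np.ndarray:
        X = _norm_matrix(adata)
        cols = [list(adata.var_names).index(g) for g in genes]
        return X[:, cols]

    Xo, Xd = extract(adata_organized), extract(adata_disrupted)
    mean_o = _cross_zone_mean(_spearman_matrix(Xo), zones)
    mean_d = _cross_zone_mean(_spearman_matrix(Xd), zones)
    stat = mean_d - mean_o

    pooled = np.vstack([Xo, Xd])
    n_o = Xo.shape[0]
    n = pooled.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        perm = rng.permutation(n)
        po = pooled[perm[:n_o]]
        pdd = pooled[perm[n_o:]]
        null[i] = _cross_zone_mean(_spearman_matrix(pdd), zones) - _cross_zone_mean(
            _spearman_matrix(po), zones
        )
    p = (1.0 + float(np.sum(null >= stat))) / (n_perm + 1.0)
    return CollapseCorrelationResult(
        statistic=float(stat),
        p_value=p,
        mean_cross_zone_organized=float(mean_o),
        mean_cross_zone_disrupted=float(mean_d),
        null=null,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Radial profiles


@dataclasses.dataclass(frozen=True)
class RadialProfile:
    """Cell densities per signed-distance bin around the lesion boundary.

    ``table`` has one row per (cell_class, bin) with columns ``lo_um``,
    ``hi_um``, ``count``, ``area_mm2``, ``density_per_mm2``; bins are
    half-open (lo, hi]. ``overflow`` counts points per class falling outside
    the binned range.
    """

    table: pd.DataFrame
    overflow: dict[str, int]
    bin_edges: tuple[float, ...]


def radial_density(
    points: pd.DataFrame,
    geometry,
    bin_edges: tuple[float, ...] | None = None,
) -> RadialProfile:
    """Bin labeled points by signed boundary distance and convert to density.

    ``points`` needs columns ``x_um``, ``y_um``, ``cell_class``; ``geometry``
    is a :class:`~rizmap.geometry.DiskGeometry` (analytic areas) or
    :class:`~rizmap.geometry.LatticeGeometry` (tile-count areas). A point
    exactly on the boundary (d = 0) falls in the innermost inside bin
    touching 0. Points outside the binned range are counted in the overflow
    bucket, so bin counts plus overflow conserve the total.
    """
    edges = np.asarray(bin_edges if bin_edges is not None else DEFAULT_BIN_EDGES, float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise InvalidConfigurationError("bin edges must be increasing with >= 2 values")
    classes = sorted(points["cell_class"].unique()) if len(points) else []
    if len(points):
        d, _ = geometry.signed_distance(points[["x_um", "y_um"]].to_numpy(float))
    else:
        d = np.empty(0)
    # (lo, hi] binning: index i such that edges[i] < d <= edges[i+1]
    idx = np.searchsorted(edges, d, side="left") - 1
    in_range = (idx >= 0) & (idx < len(edges) - 1) & (d > edges[0])

    areas = np.array(
        [geometry.band_area_um2(lo, hi) / 1e6 for lo, hi in zip(edges[:-1], edges[1:])]
    )
    rows = []
    overflow: dict[str, int] = {}
    for cls in classes:
        cls_mask = (points["cell_class"] == cls).to_numpy()
        overflow[cls] = int((cls_mask & ~in_range).sum())
        for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            count = int((cls_mask & in_range & (idx == b)).sum())
            area = areas[b]
            rows.append(
                {
                    "cell_class": cls,
                    "lo_um": lo,
                    "hi_um": hi,
                    "count": count,
                    "area_mm2": area,
                    "density_per_mm2": count / area if area > 0 else np.nan,
                }
            )
    table = pd.DataFrame(
        rows, columns=["cell_class", "lo_um", "hi_um", "count", "area_mm2", "density_per_mm2"]
    )
    return RadialProfile(table=table, overflow=overflow, bin_edges=tuple(edges))


def mean_boundary_distance(
    points: pd.DataFrame,
    geometry,
    cell_class: str,
    max_abs_um: float = 500.0,
) -> float | None:
    """Mean signed boundary distance of one cell class, within +-max_abs_um.

    Returns None (missing) when no point of the class qualifies.
    """
    sel = points[points["cell_class"] == cell_class]
    if len(sel) == 0:
        return None
    d, _ = geometry.signed_distance(sel[["x_um", "y_um"]].to_numpy(float))
    d = d[np.abs(d) <= max_abs_um]
    if len(d) == 0:
        return None
    return float(np.mean(d))


# ---------------------------------------------------------------------------
# Proximity


@dataclasses.dataclass(frozen=True)
class ProximityResult:
    """Nearest-neighbor proximity fraction and its enrichment null."""

    fraction: float
    p_value: float | None
    d_max_um: float
    n_x: int
    n_y: int
    null: np.ndarray | None = None


def proximity_fraction(
    points_x: np.ndarray | pd.DataFrame,
    points_y: np.ndarray | pd.DataFrame,
    points_other: np.ndarray | pd.DataFrame | None = None,
    d_max_um: float = 20.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> ProximityResult:
    """Fraction of X points whose nearest Y point lies within ``d_max_um``.

    With ``points_other`` (a competing class of the same kind as X, e.g.
    GPNMB-negative vs GPNMB-positive macrophages), an enrichment p-value is
    computed by relabeling the pooled X+other positions ``n_perm`` times and
    recomputing the fraction for the relabeled X set; one-sided
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``. The fraction is
    monotone non-decreasing in ``d_max_um``.
    """

    def as_xy(p) -> np.ndarray:
        if isinstance(p, pd.DataFrame):
            return p[["x_um", "y_um"]].to_numpy(float)
        return np.atleast_2d(np.asarray(p, dtype=float))

    X, Y = as_xy(points_x), as_xy(points_y)
    if len(Y) == 0:
        raise InvalidConfigurationError("reference point set Y must be non-empty")
    if len(X) == 0:
        raise InvalidConfigurationError("point set X must be non-empty")
    tree = cKDTree(Y)
    dx, _ = tree.query(X)
    frac = float(np.mean(dx <= d_max_um))
    if points_other is None:
        return ProximityResult(frac, None, float(d_max_um), len(X), len(Y))

    other = as_xy(points_other)
    d_other, _ = tree.query(other)
    pooled_near = np.concatenate([dx, d_other]) <= d_max_um
    n_x = len(X)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled_near))
        null[i] = float(np.mean(pooled_near[perm[:n_x]]))
    p = (1.0 + float(np.sum(null >= frac))) / (n_perm + 1.0)
    return ProximityResult(frac, p, float(d_max_um), n_x, len(Y), null=null)
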