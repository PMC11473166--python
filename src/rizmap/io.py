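"""Readers and writers for the on-disk formats.

Datasets are exchanged in the Space Ranger dialect: a MatrixMarket gene x spot
count matrix (``matrix.mtx``, optionally gzipped) with ``genes.tsv`` and
``barcodes.tsv`` sidecars, plus a ``tissue_positions`` CSV (both the
headerless pre-v2 and the headered v2 column orders are accepted). Pixel
coordinates are converted to um via ``um_per_px``.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import InputFormatError, InvalidConfigurationError
from .lattice import HEX_ROW_PITCH, SpotLattice

logger = logging.getLogger(__name__)

POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def write_spot_dataset(
    out_dir: str | Path, lattice: SpotLattice, adata: ad.AnnData
) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + positions.csv.

    The matrix is written gene x spot with integer counts (the ``counts``
    layer when present, else ``X``). Positions use the v2 headered
    ``tissue_positions`` column order with um coordinates (um_per_px = 1):
    ``pxl_row_in_fullres`` carries y, ``pxl_col_in_fullres`` carries x.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.layers.get("counts", adata.X)
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    mat = sparse.csr_matrix(X.T).astype(np.int64)  # genes x spots
    scipy_io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in adata.var_names))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))
    pos = pd.DataFrame(
        {
            "barcode": lattice.spot_ids,
            "in_tissue": lattice.spots["in_tissue"].astype(int).to_numpy(),
            "array_row": lattice.spots["array_row"].to_numpy(),
            "array_col": lattice.spots["array_col"].to_numpy(),
            "pxl_row_in_fullres": lattice.spots["y_um"].to_numpy(),
            "pxl_col_in_fullres": lattice.spots["x_um"].to_numpy(),
        }
    )
    # %.17g round-trips float64 exactly through text
    pos.to_csv(out / "positions.csv", index=False, float_format="%.17g")


def _find(matrix_dir: Path, names: list[str]) -> Path:
    for name in names:
        for cand in (matrix_dir / name, matrix_dir / (name + ".gz")):
            if cand.exists():
                return cand
    raise InputFormatError(f"none of {names} found in {matrix_dir}")


def _read_mtx(path: Path) -> sparse.csr_matrix:
    try:
        if path.suffix == ".gz":
            with gzip.open(path, "rb") as fh:
                mat = scipy_io.mmread(fh)
        else:
            mat = scipy_io.mmread(str(path))
    except ValueError as exc:
        raise InputFormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
    return sparse.csr_matrix(mat)


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_positions(path: Path) -> pd.DataFrame:
    with (gzip.open(path, "rt") if path.suffix == ".gz" else open(path)) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    pos = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=None if has_header else POSITIONS_COLUMNS,
        float_precision="round_trip",
    )
    if has_header:
        pos.columns = [c.strip().lower() for c in pos.columns]
        missing = [c for c in POSITIONS_COLUMNS if c not in pos.columns]
        if missing:
            raise InputFormatError(f"positions file {path} lacks columns {missing}")
    return pos[POSITIONS_COLUMNS]


def _infer_lattice_kind(spots: pd.DataFrame, spacing_um: float) -> str:
    """Hex vs square from the row pitch: sqrt(3)/2 * s pitch means hex."""
    rows = spots.groupby("array_row")["y_um"].mean().sort_index()
    if len(rows) < 2:
        return "square"
    pitch = float(np.median(np.diff(rows.to_numpy())))
    return "hex" if pitch < 0.95 * spacing_um else "square"


def read_spot_dataset(
    matrix_dir: str | Path,
    positions_path: str | Path | None = None,
    um_per_px: float = 1.0,
    lattice_kind: str | None = None,
) -> tuple[SpotLattice, ad.AnnData]:
    """Read a spot dataset (MTX triplet + positions CSV).

    Barcodes are matched one-to-one between the matrix and the positions
    table; unmatched barcodes on either side are dropped with a logged count,
    and zero matches is a fatal :class:`InputFormatError`. Lattice kind is
    inferred from the row-pitch geometry unless given; spacing is the minimum
    nearest-neighbor centroid distance.
    """
    matrix_dir = Path(matrix_dir)
    if not (um_per_px > 0):
        raise InvalidConfigurationError("um_per_px must be positive")
    mat = _read_mtx(_find(matrix_dir, ["matrix.mtx"]))
    genes = _read_lines(_find(matrix_dir, ["genes.tsv", "features.tsv"]))
    barcodes = _read_lines(_find(matrix_dir, ["barcodes.tsv"]))
    if mat.shape != (len(genes), len(barcodes)):
        raise InputFormatError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    if positions_path is None:
        positions_path = _find(matrix_dir, ["positions.csv", "tissue_positions.csv", "tissue_positions_list.csv"])
    pos = _read_positions(Path(positions_path))

    pos = pos.set_index("barcode")
    matched = [b for b in barcodes if b in pos.index]
    n_unmatched = (len(barcodes) - len(matched)) + (len(pos) - len(matched))
    if not matched:
        raise InputFormatError(
            "zero barcodes matched between the matrix and the positions table"
        )
    if n_unmatched:
        logger.warning("%d unmatched barcodes dropped", n_unmatched)

    keep = [i for i, b in enumerate(barcodes) if b in pos.index]
    mat = sparse.csr_matrix(mat[:, keep])
    pos = pos.loc[matched]

    spots = pd.DataFrame(
        {
            "x_um": pos["pxl_col_in_fullres"].to_numpy(float) * um_per_px,
            "y_um": pos["pxl_row_in_fullres"].to_numpy(float) * um_per_px,
            "array_row": pos["array_row"].to_numpy(int),
            "array_col": pos["array_col"].to_numpy(int),
            "in_tissue": pos["in_tissue"].to_numpy(int).astype(bool),
        },
        index=pd.Index(matched, name="spot_id"),
    )
    xy = spots[["x_um", "y_um"]].to_numpy(float)
    if len(xy) > 1:
        d, _ = cKDTree(xy).query(xy, k=2)
        spacing = float(np.min(d[:, 1]))
    else:
        spacing = 1.0
    kind = lattice_kind or _infer_lattice_kind(spots, spacing)
    lattice = SpotLattice(spots, kind, spacing)

    adata = ad.AnnData(
        X=sparse.csr_matrix(mat.T),
        obs=spots.copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.obsm["spatial"] = xy
    adata.uns["lattice"] = {"kind": kind, "spacing_um": spacing}
    return lattice, adata


def read_core_spots(path: str | Path) -> list[str]:
    """Read a user-supplied lesion-core spot list (CSV, ``spot_id`` column or
    a single headerless column)."""
    df = pd.read_csv(path)
    if "spot_id" in df.columns:
        return df["spot_id"].astype(str).tolist()
    # headerless single column: the read consumed the first id as a header
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    return lines


def read_cell_points(path: str | Path) -> pd.DataFrame:
    """Read labeled cell coordinates: columns x_um, y_um, cell_class."""
    df = pd.read_csv(path)
    required = ["x_um", "y_um", "cell_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"cell points file {path} lacks columns {missing}")
    return df[required + [c for c in df.columns if c not in required]]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(path: str | Path, payload: dict) -> None:
    """Write a deterministic JSON report (sorted keys, stable float repr)."""
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
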