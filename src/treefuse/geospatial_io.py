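"""Reading crowns, rasters and point clouds, and aligning them.

Conventions
-----------
Map coordinates are in meters in a shared projected CRS.  Rasters are
indexed row-major from the north-west corner (row 0 is the northern
edge); a point belongs to the cell whose half-open interval [lo, hi)
contains it along both axes, so a point on a cell edge falls in the cell
with the larger index.

Rasters are stored as TIFF with an ESRI world-file sidecar (``.tfw``)
carrying the georeferencing; point clouds as whitespace-delimited
``x y height`` text; crown polygons as GeoJSON joined against a CSV
field table on ``individual_id``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, shape

logger = logging.getLogger(__name__)

__all__ = [
    "CrownRecord",
    "RasterTile",
    "PointCloud",
    "load_crowns",
    "clip_raster",
    "centroid_pixel",
    "split_individuals",
    "read_raster",
    "write_raster",
    "read_xyz",
    "write_xyz",
]


@dataclass(frozen=True)
class CrownRecord:
    """One labelled individual: a rectangular crown bounding box joined to
    its field-data record.  ``taxon_code`` is None for withheld test crowns."""

    individual_id: str
    taxon_code: str | None
    polygon: Polygon
    site_id: str = ""
    plot_id: str = ""

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError(f"crown {self.individual_id} has non-positive area")


@dataclass(frozen=True)
class RasterTile:
    """A raster grid anchored at its north-west corner.

    ``values`` is (rows, cols) or (rows, cols, channels); ``origin`` is the
    (x_west, y_north) map coordinate of the NW corner; ``resolution`` is
    meters per cell.
    """

    origin: tuple[float, float]
    resolution: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.values.size == 0:
            raise ValueError("raster grid is empty")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the tile extent."""
        x0, y0 = self.origin
        return (x0, y0 - self.n_rows * self.resolution, x0 + self.n_cols * self.resolution, y0)


@dataclass(frozen=True)
class PointCloud:
    """Discrete-return points as an (n, 3) array of x, y, height-above-ground."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(pts[:, 2])):
            raise ValueError("point heights must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def heights(self) -> np.ndarray:
        return self.points[:, 2]


def _as_bounding_box(geom, individual_id: str) -> Polygon:
    """Crowns are rectangular by construction; any other polygon is replaced
    by its bounding box with a warning."""
    xmin, ymin, xmax, ymax = geom.bounds
    bbox = Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])
    if abs(geom.area - bbox.area) > 1e-9 * max(bbox.area, 1.0):
        logger.warning(
            "crown %s is not rectangular; replaced by its bounding box", individual_id
        )
    return bbox


def load_crowns(vector_path, field_table_path) -> list[CrownRecord]:
    """Read crown polygons (GeoJSON) and join each to its field-data row.

    The join key is ``individual_id``.  Polygons without a field match are
    retained with an absent taxon (test-set mode) and logged.
    """
    vector_path = Path(vector_path)
    gj = json.loads(vector_path.read_text())
    table = pd.read_csv(field_table_path, dtype={"individual_id": str})
    if "individual_id" not in table.columns:
        raise ValueError("field table lacks the individual_id join key")
    table = table.set_index("individual_id")

    records: list[CrownRecord] = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "individual_id" not in props:
            raise ValueError("crown feature lacks the individual_id join key")
        ind = str(props["individual_id"])
        geom = shape(feat["geometry"])
        poly = _as_bounding_box(geom, ind)
        taxon = site = plot = None
        if ind in table.index:
            row = table.loc[ind]
            raw = row.get("taxon_code")
            taxon = None if pd.isna(raw) or raw == "" else str(raw)
            site = str(row.get("site_id", "") or "")
            plot = str(row.get("plot_id", "") or "")
        else:
            logger.warning("crown %s has no field-data match", ind)
        records.append(
            CrownRecord(
                individual_id=ind,
                taxon_code=taxon,
                polygon=poly,
                site_id=site or "",
                plot_id=plot or "",
            )
        )
    return records


def clip_raster(tile: RasterTile, polygon: Polygon) -> RasterTile:
    """Return the sub-grid of cells whose centers fall inside the polygon's
    bounding box (half-open on the max edges).

    Raises ``ValueError`` when no cell center falls inside.
    """
    xmin, ymin, xmax, ymax = polygon.bounds
    x0, y0 = tile.origin
    res = tile.resolution
    col_centers = x0 + (np.arange(tile.n_cols) + 0.5) * res
    row_centers = y0 - (np.arange(tile.n_rows) + 0.5) * res
    cols = np.where((col_centers >= xmin) & (col_centers < xmax))[0]
    rows = np.where((row_centers >= ymin) & (row_centers < ymax))[0]
    if len(cols) == 0 or len(rows) == 0:
        raise ValueError("polygon does not cover any cell center of the tile")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    new_origin = (x0 + c0 * res, y0 - r0 * res)
    return RasterTile(origin=new_origin, resolution=res, values=tile.values[r0:r1, c0:c1])


def centroid_pixel(tile: RasterTile, polygon: Polygon) -> tuple[int, int]:
    """(row, col) of the cell containing the polygon centroid.

    Half-open convention: a centroid exactly on a cell edge belongs to the
    cell with the larger index along that axis.
    """
    cx, cy = polygon.centroid.x, polygon.centroid.y
    x0, y0 = tile.origin
    res = tile.resolution
    col = int(np.floor((cx - x0) / res))
    row = int(np.floor((y0 - cy) / res))
    if not (0 <= row < tile.n_rows and 0 <= col < tile.n_cols):
        raise ValueError("polygon centroid lies outside the tile extent")
    return row, col


def split_individuals(records, fraction: float, seed: int):
    """Random disjoint train/holdout split at the individual level.

    |train| = round(fraction * n); deterministic given ``seed``.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    records = list(records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(fraction * len(records)))
    train = [records[i] for i in order[:n_train]]
    holdout = [records[i] for i in order[n_train:]]
    return train, holdout


# ---------------------------------------------------------------------------
# File formats


def write_raster(path, tile: RasterTile) -> None:
    """Write a TIFF plus an ESRI world file (six-line text sidecar) holding
    the cell size and the center of the upper-left cell."""
    path = Path(path)
    tifffile.imwrite(path, tile.values)
    x0, y0 = tile.origin
    res = tile.resolution
    world = "\n".join(
        str(v) for v in (res, 0.0, 0.0, -res, x0 + res / 2, y0 - res / 2)
    )
    path.with_suffix(".tfw").write_text(world + "\n")


def read_raster(path) -> RasterTile:
    path = Path(path)
    values = tifffile.imread(path)
    tfw = path.with_suffix(".tfw")
    if tfw.exists():
        a, _, _, d, cx, cy = (float(t) for t in tfw.read_text().split())
        res = a
        origin = (cx - res / 2, cy + res / 2)
    else:  # un-referenced raster: local coordinates
        res, origin = 1.0, (0.0, 0.0)
    return RasterTile(origin=origin, resolution=res, values=values)


def write_xyz(path, cloud: PointCloud) -> None:
    np.savetxt(path, cloud.points, fmt="%.4f")


def read_xyz(path) -> PointCloud:
    pts = np.loadtxt(path, ndmin=2)
    if pts.size == 0:
        pts = np.empty((0, 3))
    return PointCloud(pts)
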