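"""Gridded Shannon diversity and zonal aggregation.

Biodiversity is gridded from occurrence points (taxon, x, y) and
geodiversity from a categorical landform raster, both onto square cells
(2000 m by default): per cell, H = -sum p_i ln p_i over the taxa or class
shares observed there. Zonal aggregation reduces any value raster over
polygon zones by the cells whose centers fall inside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .raster_io import Grid, VectorLayer

__all__ = [
    "shannon_index",
    "grid_shannon_points",
    "grid_shannon_raster",
    "grid_shannon",
    "zonal_aggregate",
]


def shannon_index(counts, base: float | None = None) -> float:
    """H = -sum p_i log p_i of a count vector (natural log by default)."""
    counts = np.asarray(list(counts), dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        return float("nan")
    h = stats.entropy(counts)  # natural log
    if base is not None:
        h /= np.log(base)
    return float(h)


def grid_shannon_points(
    points: pd.DataFrame,
    cell_m: float = 2000.0,
    origin: tuple[float, float] | None = None,
    base: float | None = None,
    presence_only: bool = False,
) -> Grid:
    """Shannon diversity of occurrence points on a square lattice.

    ``points`` needs columns ``taxon``, ``x``, ``y``. Cells are half-open:
    a point on a cell's right/bottom edge belongs to the next cell. The
    lattice is anchored at ``origin`` (upper-left; defaults to the data's
    min x / max y). ``presence_only`` collapses duplicate records of a
    taxon in a cell to one before computing shares. Cells without records
    are nodata.
    """
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    if len(points) == 0:
        raise ValueError("at least one occurrence record is required")
    pts = points[["taxon", "x", "y"]].copy()
    if pts["taxon"].astype(str).str.len().eq(0).any():
        raise ValueError("taxon names must be non-empty")
    if origin is None:
        origin = (float(pts.x.min()), float(pts.y.max()))
    ox, oy = origin
    # half-open cells: a point on a cell's right/bottom edge belongs to the
    # next cell (floor of the offset in cell units)
    col = np.floor((pts.x.to_numpy() - ox) / cell_m).astype(int)
    row = np.floor((oy - pts.y.to_numpy()) / cell_m).astype(int)
    keep = (col >= 0) & (row >= 0)
    pts = pts.assign(row=row, col=col)[keep]
    nrows = int(pts.row.max()) + 1
    ncols = int(pts.col.max()) + 1
    out = np.full((nrows, ncols), -9999.0)
    grouped = pts.groupby(["row", "col"])
    for (r, c), sub in grouped:
        if presence_only:
            counts = np.ones(sub.taxon.nunique())
        else:
            counts = sub.taxon.value_counts().to_numpy()
        out[r, c] = shannon_index(counts, base=base)
    return Grid(out, cellsize=cell_m, origin=(ox, oy), nodata=-9999.0)


def grid_shannon_raster(
    class_raster: Grid,
    cell_m: float = 2000.0,
    base: float | None = None,
) -> Grid:
    """Shannon diversity of a categorical raster aggregated to coarse cells.

    Shares are cell-count shares of each class code within every
    ``cell_m`` x ``cell_m`` block of the input lattice.
    """
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    block = max(1, int(round(cell_m / class_raster.cellsize)))
    nrows = int(np.ceil(class_raster.nrows / block))
    ncols = int(np.ceil(class_raster.ncols / block))
    out = np.full((nrows, ncols), class_raster.nodata)
    valid = class_raster.mask()
    for i in range(nrows):
        for j in range(ncols):
            sl = (slice(i * block, (i + 1) * block),
                  slice(j * block, (j + 1) * block))
            vals = class_raster.values[sl][valid[sl]]
            if vals.size:
                _, counts = np.unique(vals, return_counts=True)
                out[i, j] = shannon_index(counts, base=base)
    return Grid(out, cellsize=block * class_raster.cellsize,
                origin=class_raster.origin, nodata=class_raster.nodata,
                crs_label=class_raster.crs_label)


def grid_shannon(source, cell_m: float = 2000.0, **kwargs) -> Grid:
    """Dispatch to the point-based or raster-based diversity gridder."""
    if isinstance(source, Grid):
        return grid_shannon_raster(source, cell_m, **kwargs)
    return grid_shannon_points(source, cell_m, **kwargs)


def zonal_aggregate(values: Grid, zones: VectorLayer,
                    stat: str = "mean") -> pd.DataFrame:
    """Reduce a raster over polygon zones by cell-center membership.

    Returns a DataFrame with ``zone_id``, the statistic, and the number of
    contributing cells; a zone covering no valid cell center yields NaN.
    """
    if stat not in ("mean", "max", "sum"):
        raise ValueError(f"unknown statistic {stat!r}")
    from shapely.geometry import Point
    from shapely.prepared import prep

    ox, oy = values.origin
    cs = values.cellsize
    valid = values.mask()
    rows_out = []
    for zid, (geom, attrs) in enumerate(zones, start=1):
        if not geom.is_valid:
            raise ValueError(f"invalid polygon for zone {zid}")
        pg = prep(geom)
        cells = []
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int((minx - ox) // cs))
        c1 = min(values.ncols, int(np.ceil((maxx - ox) / cs)) + 1)
        r0 = max(0, int((oy - maxy) // cs))
        r1 = min(values.nrows, int(np.ceil((oy - miny) / cs)) + 1)
        for r in range(r0, r1):
            for c in range(c0, c1):
                if not valid[r, c]:
                    continue
                if pg.contains(Point(ox + (c + 0.5) * cs, oy - (r + 0.5) * cs)):
                    cells.append(values.values[r, c])
        arr = np.asarray(cells)
        agg = (float(getattr(np, stat)(arr)) if arr.size else float("nan"))
        rows_out.append({"zone_id": attrs.get("zone_id", zid),
                         stat: agg, "n_cells": int(arr.size)})
    return pd.DataFrame(rows_out)
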