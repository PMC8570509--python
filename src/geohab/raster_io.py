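"""Raster data model, file I/O, focal smoothing and resampling.

The :class:`Grid` is the universal single-band carrier for every raster in
the toolkit: DEM elevations (m), NDVI, categorical class codes, flow fields.
Values are cell-centered, north-up: row index increases southward, the
``origin`` is the outer (upper-left) corner of cell (0, 0), and all distance
math uses cell centers.

Supported on-disk formats are ESRI ASCII grid (``.asc``) and single-band
GeoTIFF (via :mod:`tifffile`, with ModelPixelScale / ModelTiepoint /
GDAL-nodata tags).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "VectorLayer",
    "RasterIOError",
    "GridAlignmentError",
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "low_pass_filter",
    "resample",
]

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes used for georeferencing a plain TIFF.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterIOError(Exception):
    """Raised for unreadable files, unsupported formats, or bad headers."""


class GridAlignmentError(Exception):
    """Raised when an overlay operation receives grids on different lattices."""


@dataclass
class Grid:
    """A georeferenced single-band raster.

    Parameters
    ----------
    values:
        2-D float array, shape ``(nrows, ncols)``. Nodata cells carry
        ``nodata`` (NaN is also treated as nodata on input and normalised).
    cellsize:
        Edge length of a square cell in meters.
    origin:
        ``(x, y)`` map coordinates of the upper-left corner of the grid.
    nodata:
        Sentinel value for missing cells.
    crs_label:
        Free-text coordinate-system tag; overlay ops require equal labels.
    """

    values: np.ndarray
    cellsize: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA
    crs_label: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("Grid values must be a non-empty 2-D array")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")
        # normalise NaNs to the nodata sentinel
        nan = np.isnan(self.values)
        if nan.any():
            self.values = np.where(nan, self.nodata, self.values)
        valid = self.values != self.nodata
        if not np.isfinite(self.values[valid]).all():
            raise ValueError("non-nodata values must be finite")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        return self.values != self.nodata

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN (for numpy reductions)."""
        return np.where(self.mask(), self.values, np.nan)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each (nrows, ncols)."""
        ox, oy = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = ox + (cols + 0.5) * self.cellsize
        y = oy - (rows + 0.5) * self.cellsize
        return np.meshgrid(x, y)[0], np.meshgrid(x, y)[1]

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new grid on the same lattice carrying ``values``."""
        return Grid(
            np.asarray(values, dtype=float),
            cellsize=self.cellsize,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
            crs_label=self.crs_label,
        )

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())


def ensure_aligned(*grids: Grid, context: str = "overlay") -> None:
    """Raise :class:`GridAlignmentError` unless all grids share one lattice."""
    ref = grids[0]
    for g in grids[1:]:
        if (
            g.shape != ref.shape
            or not math.isclose(g.cellsize, ref.cellsize)
            or not np.allclose(g.origin, ref.origin)
            or g.crs_label != ref.crs_label
        ):
            raise GridAlignmentError(
                f"{context}: grids are not co-registered "
                f"(shape {ref.shape} vs {g.shape}, cellsize {ref.cellsize} vs "
                f"{g.cellsize}, origin {ref.origin} vs {g.origin}, "
                f"crs {ref.crs_label!r} vs {g.crs_label!r})"
            )


@dataclass
class VectorLayer:
    """Shapely geometries with per-geometry attribute dicts.

    Used for lakes (polygons), administrative zones (polygons), occurrence
    or pour points (points) and divide candidates, all in the grid's
    coordinate space.
    """

    geometries: list = field(default_factory=list)
    attributes: list = field(default_factory=list)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValueError("one attribute dict per geometry required")

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self):
        return iter(zip(self.geometries, self.attributes))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_raster(path: str | os.PathLike) -> Grid:
    """Read an ESRI ASCII grid or single-band GeoTIFF."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise RasterIOError(f"raster file not found: {path}")
    low = path.lower()
    if low.endswith((".asc", ".txt")):
        return _read_ascii(path)
    if low.endswith((".tif", ".tiff")):
        return _read_geotiff(path)
    raise RasterIOError(f"unsupported raster format: {path}")


def write_raster(grid: Grid, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    low = path.lower()
    if low.endswith((".asc", ".txt")):
        _write_ascii(grid, path)
    elif low.endswith((".tif", ".tiff")):
        _write_geotiff(grid, path)
    else:
        raise RasterIOError(f"unsupported raster format: {path}")


def _read_ascii(path: str) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
                line = fh.readline()
            else:
                break
        fh.seek(pos)
        try:
            values = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise RasterIOError(f"malformed ASCII grid body in {path}: {exc}")
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterIOError(f"ASCII grid {path} missing header key {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise RasterIOError(
            f"ASCII grid {path}: body shape {values.shape} does not match "
            f"header ({nrows}, {ncols})"
        )
    cellsize = header["cellsize"]
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    # ASCII header gives the lower-left corner; Grid stores the upper-left.
    origin = (xll, yll + nrows * cellsize)
    return Grid(values, cellsize=cellsize, origin=origin, nodata=nodata)


def _write_ascii(grid: Grid, path: str) -> None:
    ox, oy = grid.origin
    yll = oy - grid.nrows * grid.cellsize
    with open(path, "w") as fh:
        fh.write(f"NCOLS {grid.ncols}\n")
        fh.write(f"NROWS {grid.nrows}\n")
        fh.write(f"XLLCORNER {ox!r}\n")
        fh.write(f"YLLCORNER {yll!r}\n")
        fh.write(f"CELLSIZE {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: str) -> Grid:
    import tifffile

    cellsize = 1.0
    origin = (0.0, 0.0)
    nodata = DEFAULT_NODATA
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            if _TAG_MODEL_PIXEL_SCALE in tags:
                sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
                if not math.isclose(sx, sy):
                    raise RasterIOError(
                        f"GeoTIFF {path}: non-square cells unsupported")
                cellsize = float(sx)
            if _TAG_MODEL_TIEPOINT in tags:
                # tiepoint maps raster (i, j) -> model (x, y); written at (0, 0)
                tp = tags[_TAG_MODEL_TIEPOINT].value
                origin = (float(tp[3]) - float(tp[0]) * cellsize,
                          float(tp[4]) + float(tp[1]) * cellsize)
            if _TAG_GDAL_NODATA in tags:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value)
                               .strip("\x00 "))
    except RasterIOError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise RasterIOError(f"cannot read GeoTIFF {path}: {exc}")
    if values.ndim != 2:
        raise RasterIOError(f"GeoTIFF {path} is not single-band")
    return Grid(values, cellsize=cellsize, origin=origin, nodata=nodata)


def _write_geotiff(grid: Grid, path: str) -> None:
    import tifffile

    ox, oy = grid.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cellsize, grid.cellsize, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float32), extratags=extratags)


def read_vector(path: str | os.PathLike) -> VectorLayer:
    """Read a GeoJSON FeatureCollection into a :class:`VectorLayer`."""
    from shapely.geometry import shape

    path = os.fspath(path)
    if not os.path.exists(path):
        raise RasterIOError(f"vector file not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    geoms = [shape(f["geometry"]) for f in feats]
    attrs = [dict(f.get("properties") or {}) for f in feats]
    return VectorLayer(geoms, attrs)


def write_vector(layer: VectorLayer, path: str | os.PathLike) -> None:
    from shapely.geometry import mapping

    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": a}
            for g, a in layer
        ],
    }
    with open(os.fspath(path), "w") as fh:
        json.dump(doc, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# focal smoothing and resampling
# ---------------------------------------------------------------------------

def low_pass_filter(
    dem: Grid,
    window: int | tuple[int, int] = (10, 10),
    kernel: str = "mean",
    sigma: float | None = None,
) -> Grid:
    """Smooth a DEM with a focal mean (or Gaussian) filter.

    ``window`` may be odd or even. Even windows have no center cell; the
    output cell sits at the upper-left of the window's central 2x2 block
    (window index ``(w-1)//2`` on each axis), the common GIS
    focal-statistics convention. Nodata cells are excluded from the mean; a
    cell whose whole window is nodata stays nodata.

    ``kernel='gaussian'`` applies a Gaussian of scale ``sigma`` (default
    ``window/4``) truncated at the window size instead of a flat mean.
    """
    wr, wc = (window, window) if isinstance(window, int) else window
    if wr < 1 or wc < 1:
        raise ValueError("window must be >= 1 in both dimensions")
    if wr > dem.nrows or wc > dem.ncols:
        raise ValueError(
            f"window {wr}x{wc} exceeds grid extent {dem.nrows}x{dem.ncols}"
        )
    if kernel == "mean":
        weights = np.ones((wr, wc))
    elif kernel == "gaussian":
        s = sigma if sigma is not None else max(wr, wc) / 4.0
        ri = np.arange(wr) - (wr - 1) / 2.0
        ci = np.arange(wc) - (wc - 1) / 2.0
        rr, cc = np.meshgrid(ri, ci, indexing="ij")
        weights = np.exp(-(rr**2 + cc**2) / (2.0 * s**2))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    valid = dem.mask()
    vals = np.where(valid, dem.values, 0.0)
    # scipy's correlate places the window over [i-(w-1)//2, i+w//2], which
    # anchors even windows at the upper-left of the central block — exactly
    # the anchoring documented above — so no origin shift is needed.
    num = ndimage.correlate(vals, weights, mode="constant", cval=0.0)
    den = ndimage.correlate(valid.astype(float), weights, mode="constant",
                            cval=0.0)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), dem.nodata)
    return dem.like(out)


def resample(grid: Grid, target_cellsize: float, method: str = "nearest") -> Grid:
    """Resample to a new cell size, preserving extent within one target cell.

    ``method='mean'`` averages the source cells falling in each target cell
    and is only defined for coarsening; use ``'nearest'`` to upsample.
    """
    if not target_cellsize > 0:
        raise ValueError("target_cellsize must be positive")
    if method not in ("nearest", "mean"):
        raise ValueError(f"unknown resampling method {method!r}")
    factor = target_cellsize / grid.cellsize
    if method == "mean" and factor < 1.0:
        raise ValueError("mean resampling only supports coarsening; "
                         "use method='nearest' to upsample")
    n_out_r = max(1, int(round(grid.nrows / factor)))
    n_out_c = max(1, int(round(grid.ncols / factor)))

    if method == "nearest":
        src_r = np.minimum((np.arange(n_out_r) + 0.5) * factor,
                           grid.nrows - 0.5).astype(int)
        src_c = np.minimum((np.arange(n_out_c) + 0.5) * factor,
                           grid.ncols - 0.5).astype(int)
        out = grid.values[np.ix_(src_r, src_c)]
    else:
        out = np.full((n_out_r, n_out_c), grid.nodata)
        valid = grid.mask()
        edges_r = np.minimum(np.round(np.arange(n_out_r + 1) * factor).astype(int),
                             grid.nrows)
        edges_c = np.minimum(np.round(np.arange(n_out_c + 1) * factor).astype(int),
                             grid.ncols)
        for i in range(n_out_r):
            r0, r1 = edges_r[i], max(edges_r[i + 1], edges_r[i] + 1)
            for j in range(n_out_c):
                c0, c1 = edges_c[j], max(edges_c[j + 1], edges_c[j] + 1)
                block = grid.values[r0:r1, c0:c1]
                ok = valid[r0:r1, c0:c1]
                if ok.any():
                    out[i, j] = block[ok].mean()
    return Grid(out, cellsize=target_cellsize, origin=grid.origin,
                nodata=grid.nodata, crs_label=grid.crs_label)
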