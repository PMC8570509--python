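"""NDVI, water masking, lake inflows and the wetland candidate rule.

A cell is a wetland candidate when it is gentle (slope <= 5 degrees by
default), near a lake (cell center within 200 m of the lake boundary), has
NDVI in the moist-vegetation band [-0.2, 0.3], and is not itself inside the
lake. Contiguous candidates (8-connectivity) are merged into polygons with
summary attributes; an external review file can set a per-candidate
verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster_io import Grid, VectorLayer, ensure_aligned

__all__ = [
    "WetlandParams",
    "WetlandCandidateSet",
    "ndvi",
    "water_mask",
    "lake_inflow_points",
    "wetland_candidates",
]

WATER, LAND = 1.0, 0.0


@dataclass(frozen=True)
class WetlandParams:
    slope_max_deg: float = 5.0
    buffer_m: float = 200.0
    ndvi_min: float = -0.2
    ndvi_max: float = 0.3


@dataclass
class WetlandCandidateSet:
    """Merged candidate polygons with per-candidate attributes."""

    polygons: VectorLayer
    cell_mask: np.ndarray          # True on candidate cells
    params: WetlandParams

    def __len__(self) -> int:
        return len(self.polygons)

    def set_verdicts(self, review: dict[int, str]) -> None:
        """Apply an external review: candidate id -> verdict string."""
        for geom, attrs in self.polygons:
            cid = attrs["candidate_id"]
            if cid in review:
                attrs["verdict"] = review[cid]


def ndvi(red: Grid, nir: Grid) -> Grid:
    """(NIR - red) / (NIR + red) per cell; zero denominators become nodata."""
    ensure_aligned(red, nir, context="ndvi")
    valid = red.mask() & nir.mask()
    if (red.values[valid] < 0).any() or (nir.values[valid] < 0).any():
        raise ValueError("reflectances must be non-negative")
    den = red.values + nir.values
    ok = valid & (den > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (nir.values - red.values) / np.where(ok, den, 1.0)
    out = np.where(ok, v, red.nodata)
    return red.like(out)


def water_mask(ndvi_grid: Grid) -> Grid:
    """Water where NDVI <= 0 (inclusive), land elsewhere; nodata passes."""
    valid = ndvi_grid.mask()
    out = np.where(ndvi_grid.values <= 0.0, WATER, LAND)
    out = np.where(valid, out, ndvi_grid.nodata)
    return ndvi_grid.like(out)


def lake_inflow_points(net, lakes: VectorLayer, fdir: Grid) -> VectorLayer:
    """Stream endpoints on lake boundaries, flagged inflow or outflow.

    A stream cell adjacent to (or inside) a lake whose upstream side is
    outside the lake is an inflow; a stream cell inside the lake draining
    to a cell outside is an outflow. Returned as cell-center points with
    ``lake_id`` and ``kind`` attributes.
    """
    from shapely.geometry import Point

    from .hydrology import downstream_index

    if net.is_empty() or len(lakes) == 0:
        return VectorLayer([], [], crs_label=fdir.crs_label)
    ncols = fdir.ncols
    ox, oy = fdir.origin
    cs = fdir.cellsize
    down = downstream_index(fdir)
    stream_cells = sorted(net.order.keys())

    def center(i: int) -> Point:
        return Point(ox + (i % ncols + 0.5) * cs, oy - (i // ncols + 0.5) * cs)

    def lake_of(pt: Point) -> int | None:
        for lid, (geom, attrs) in enumerate(lakes):
            if geom.buffer(1e-9).covers(pt):
                return attrs.get("lake_id", lid + 1)
        return None

    geoms, attrs = [], []
    in_lake = {i: lake_of(center(i)) for i in stream_cells}
    for i in stream_cells:
        j = down[i // ncols, i % ncols]
        here, there = in_lake.get(i), in_lake.get(j) if j >= 0 else None
        if j >= 0 and j in in_lake and here is None and there is not None:
            geoms.append(center(j))
            attrs.append({"lake_id": there, "kind": "inflow",
                          "row": j // ncols, "col": j % ncols})
        elif here is not None and (j < 0 or there is None):
            geoms.append(center(i))
            attrs.append({"lake_id": here, "kind": "outflow",
                          "row": i // ncols, "col": i % ncols})
    return VectorLayer(geoms, attrs, crs_label=fdir.crs_label)


def wetland_candidates(
    slope_deg: Grid,
    lakes: VectorLayer,
    ndvi_grid: Grid,
    params: WetlandParams | None = None,
) -> WetlandCandidateSet:
    """Apply the three-predicate lake-margin wetland rule cell-wise.

    Candidate cells satisfy slope <= ``slope_max_deg``, center-to-lake-
    boundary distance <= ``buffer_m`` (Euclidean, to the nearest boundary
    vertex/segment), NDVI within ``[ndvi_min, ndvi_max]``, and lie outside
    the lake polygon. 8-connected candidate cells merge into one polygon
    carrying mean slope, mean NDVI, minimum lake distance and an initial
    ``verdict`` of ``"candidate"``.
    """
    from shapely.geometry import Point, box
    from shapely.ops import unary_union

    params = params or WetlandParams()
    ensure_aligned(slope_deg, ndvi_grid, context="wetland_candidates")
    nrows, ncols = slope_deg.shape
    if len(lakes) == 0:
        return WetlandCandidateSet(
            VectorLayer([], [], crs_label=slope_deg.crs_label),
            np.zeros((nrows, ncols), dtype=bool), params)
    ox, oy = slope_deg.origin
    cs = slope_deg.cellsize
    boundaries = [geom.boundary for geom, _ in lakes]
    lake_union = unary_union([geom for geom, _ in lakes])

    valid = slope_deg.mask() & ndvi_grid.mask()
    dist = np.full((nrows, ncols), np.inf)
    inside = np.zeros((nrows, ncols), dtype=bool)
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            pt = Point(ox + (c + 0.5) * cs, oy - (r + 0.5) * cs)
            dist[r, c] = min(b.distance(pt) for b in boundaries)
            inside[r, c] = lake_union.contains(pt)
    cand = (
        valid
        & ~inside
        & (slope_deg.values <= params.slope_max_deg)
        & (dist <= params.buffer_m)
        & (ndvi_grid.values >= params.ndvi_min)
        & (ndvi_grid.values <= params.ndvi_max)
    )
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    geoms, attrs = [], []
    for cid in range(1, n + 1):
        rr, cc = np.nonzero(labels == cid)
        cells = [box(ox + c * cs, oy - (r + 1) * cs,
                     ox + (c + 1) * cs, oy - r * cs)
                 for r, c in zip(rr, cc)]
        geoms.append(unary_union(cells))
        attrs.append({
            "candidate_id": cid,
            "n_cells": int(len(rr)),
            "mean_slope_deg": float(slope_deg.values[rr, cc].mean()),
            "mean_ndvi": float(ndvi_grid.values[rr, cc].mean()),
            "min_lake_distance_m": float(dist[rr, cc].min()),
            "verdict": "candidate",
        })
    layer = VectorLayer(geoms, attrs, crs_label=slope_deg.crs_label)
    return WetlandCandidateSet(layer, cand, params)
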