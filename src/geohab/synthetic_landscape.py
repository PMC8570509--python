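"""Synthetic landscapes, spectral bands, communities and environment tables.

Every generator is a pure, seeded function of its spec, so each pipeline
stage can be exercised against known ground truth: DEMs are sums of a base
plane and Gaussian features (hills, basins, ridges, valleys, plateaus),
red/NIR band pairs are constructed to hit requested NDVI means per elevation
zone, site-by-species tables plant indicator species with known specificity
and fidelity, and environment tables follow an explicit factor model
``x = L f + eps``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .raster_io import Grid

__all__ = [
    "LandscapeSpec",
    "Feature",
    "CommunitySpec",
    "FactorSpec",
    "make_dem",
    "make_ndvi",
    "make_lakes",
    "make_community",
    "make_env_table",
    "ENV_VARIABLES",
]

# the 11 terrain/climate/diversity variables of the habitat factor analysis
ENV_VARIABLES = [
    "elev", "elevmax", "precipt", "temper", "biodiv", "geodiv",
    "cold", "cont", "warm", "slope", "aspect",
]


@dataclass
class Feature:
    """One landscape element superposed on the base plane.

    ``kind`` hill/plateau add relief (+amplitude); basin/valley subtract.
    Ridges and valleys are Gaussian profiles extruded along a segment from
    ``center`` to ``end`` (grid row/col coordinates); hills, basins and
    plateaus are isotropic bumps centred at ``center``. ``width`` is the
    Gaussian sigma in meters (plateaus use a flattened super-Gaussian).
    """

    kind: str
    center: tuple[float, float]
    amplitude: float
    width: float
    end: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("hill", "basin", "ridge", "valley", "plateau"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("feature amplitude and width must be positive")


@dataclass
class LandscapeSpec:
    nrows: int = 64
    ncols: int = 64
    cellsize: float = 30.0
    base_elevation: float = 100.0
    base_slope: float = 0.0        # meters per cell along the dip azimuth
    base_azimuth_deg: float = 180.0  # downhill direction, clockwise from N
    features: list[Feature] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0


def make_dem(spec: LandscapeSpec) -> Grid:
    """Build a DEM from the spec: plane + Gaussian features + noise.

    Deterministic for a fixed seed; with ``noise_sd == 0`` the surface is an
    exact closed form, so feature maxima are known (a lone hill of amplitude
    A peaks at base + A at its center cell).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.meshgrid(np.arange(spec.nrows), np.arange(spec.ncols),
                             indexing="ij")
    az = np.deg2rad(spec.base_azimuth_deg)
    # distance along the dip azimuth in cells; north-up, so row index grows
    # southward and azimuth 180 deg (due south) means downhill = +rows
    along = -rows * np.cos(az) + cols * np.sin(az)
    z = spec.base_elevation - spec.base_slope * along

    for f in spec.features:
        w_cells = f.width / spec.cellsize
        if w_cells * 2 > max(spec.nrows, spec.ncols):
            warnings.warn(
                f"feature {f.kind} wider than the grid; generated anyway")
        if f.kind in ("hill", "basin", "plateau"):
            d2 = (rows - f.center[0]) ** 2 + (cols - f.center[1]) ** 2
            if f.kind == "plateau":
                bump = np.exp(-((d2 / (2 * w_cells**2)) ** 3))
            else:
                bump = np.exp(-d2 / (2 * w_cells**2))
            sign = -1.0 if f.kind == "basin" else 1.0
        else:  # ridge / valley: distance to the segment center->end
            end = f.end if f.end is not None else f.center
            d2 = _dist2_to_segment(rows, cols, f.center, end)
            bump = np.exp(-d2 / (2 * w_cells**2))
            sign = -1.0 if f.kind == "valley" else 1.0
        z = z + sign * f.amplitude * bump

    if spec.noise_sd > 0:
        z = z + rng.normal(0.0, spec.noise_sd, z.shape)
    return Grid(z, cellsize=spec.cellsize, origin=(0.0, 0.0))


def _dist2_to_segment(rows, cols, a, b):
    ar, ac = a
    br, bc = b
    vr, vc = br - ar, bc - ac
    vv = vr * vr + vc * vc
    if vv == 0:
        return (rows - ar) ** 2 + (cols - ac) ** 2
    t = np.clip(((rows - ar) * vr + (cols - ac) * vc) / vv, 0.0, 1.0)
    pr, pc = ar + t * vr, ac + t * vc
    return (rows - pr) ** 2 + (cols - pc) ** 2


def make_ndvi(
    dem: Grid,
    wetness_rule: Sequence[tuple[float, float]] = ((0.1, -0.5), (1.0, 0.4)),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Grid, Grid]:
    """Construct co-registered red and NIR bands with controlled NDVI.

    ``wetness_rule`` is a list of ``(elevation_quantile, ndvi_mean)`` pairs:
    cells whose DEM value falls at or below the given elevation quantile
    (and above the previous one) get that NDVI mean. Bands are built as
    red = (1 - v)/2, nir = (1 + v)/2 so ndvi(red, nir) = v exactly at zero
    noise, with reflectances in [0, 1].
    """
    rng = np.random.default_rng(seed)
    z = dem.values
    target = np.full(z.shape, wetness_rule[-1][1], dtype=float)
    prev_q = -np.inf
    flat = np.sort(z[dem.mask()])
    for q, v in wetness_rule:
        hi = np.quantile(flat, min(q, 1.0))
        lo = -np.inf if prev_q == -np.inf else np.quantile(flat, prev_q)
        sel = (z > lo) & (z <= hi) if prev_q != -np.inf else (z <= hi)
        target[sel] = v
        prev_q = q
    if noise_sd > 0:
        target = target + rng.normal(0.0, noise_sd, target.shape)
    target = np.clip(target, -0.999, 0.999)
    red = dem.like((1.0 - target) / 2.0)
    nir = dem.like((1.0 + target) / 2.0)
    return red, nir


def make_lakes(dem: Grid, level_quantile: float = 0.05):
    """Polygonise the low-elevation cells of a DEM into lake polygons.

    Cells at or below the given elevation quantile are flooded; 8-connected
    components become lake polygons (unions of cell squares). Returns a
    :class:`~geohab.raster_io.VectorLayer` of polygons with ``lake_id``.
    """
    from scipy import ndimage as ndi
    from shapely.geometry import box
    from shapely.ops import unary_union

    from .raster_io import VectorLayer

    level = np.quantile(dem.values[dem.mask()], level_quantile)
    wet = dem.mask() & (dem.values <= level)
    labels, n = ndi.label(wet, structure=np.ones((3, 3), dtype=int))
    ox, oy = dem.origin
    cs = dem.cellsize
    geoms, attrs = [], []
    for lid in range(1, n + 1):
        rr, cc = np.nonzero(labels == lid)
        cells = [box(ox + c * cs, oy - (r + 1) * cs,
                     ox + (c + 1) * cs, oy - r * cs)
                 for r, c in zip(rr, cc)]
        geoms.append(unary_union(cells))
        attrs.append({"lake_id": lid, "n_cells": int(len(rr)),
                      "level": float(level)})
    return VectorLayer(geoms, attrs, crs_label=dem.crs_label)


@dataclass
class CommunitySpec:
    """Ground-truth design for a site-by-species presence/absence table."""

    n_groups: int = 3
    sites_per_group: int = 10
    n_indicators_per_group: int = 3
    specificity_a: float = 1.0
    fidelity_b: float = 1.0
    n_noise_species: int = 20
    noise_prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("at least 2 groups required")
        for p in (self.specificity_a, self.fidelity_b, self.noise_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.specificity_a > 0:
            raise ValueError("specificity_a must be positive")


def make_community(spec: CommunitySpec) -> pd.DataFrame:
    """Generate a site x species 0/1 table with planted indicator species.

    Returns a DataFrame whose index is the site id, first column ``group``
    (site's habitat group), remaining columns one per species. A planted
    indicator of group g occurs in g's sites with probability
    ``fidelity_b``; in each other group's sites with probability
    ``q = b (1 - a) / (a (K - 1))`` so the expected group-mean-based
    specificity (the IndVal.g A component) equals ``specificity_a``.
    Noise species occur everywhere at ``noise_prevalence``.
    """
    rng = np.random.default_rng(spec.seed)
    K, m = spec.n_groups, spec.sites_per_group
    n_sites = K * m
    groups = np.repeat(np.arange(1, K + 1), m)
    a, b = spec.specificity_a, spec.fidelity_b
    q = b * (1.0 - a) / (a * (K - 1))
    if q > 1.0:
        raise ValueError("infeasible (specificity_a, fidelity_b) combination")
    cols: dict[str, np.ndarray] = {}
    for g in range(1, K + 1):
        for i in range(spec.n_indicators_per_group):
            p = np.where(groups == g, b, q)
            cols[f"ind_g{g}_{i + 1}"] = (rng.random(n_sites) < p).astype(int)
    for i in range(spec.n_noise_species):
        cols[f"noise_{i + 1}"] = (
            rng.random(n_sites) < spec.noise_prevalence).astype(int)
    table = pd.DataFrame(cols, index=[f"site_{s + 1}" for s in range(n_sites)])
    table.insert(0, "group", groups)
    return table


@dataclass
class FactorSpec:
    """Design for an environment table following x = L f + eps."""

    n_obs: int = 500
    loading_matrix: np.ndarray = None  # variables x factors
    unique_sd: np.ndarray = None       # per-variable noise sd
    variable_names: list[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loading_matrix is None:
            raise ValueError("loading_matrix is required")
        self.loading_matrix = np.atleast_2d(
            np.asarray(self.loading_matrix, dtype=float))
        n_vars = self.loading_matrix.shape[0]
        if self.unique_sd is None:
            # complete each variable to unit variance
            h2 = (self.loading_matrix**2).sum(axis=1)
            if (h2 > 1).any():
                raise ValueError("row sums of squared loadings exceed 1")
            self.unique_sd = np.sqrt(1.0 - h2)
        self.unique_sd = np.asarray(self.unique_sd, dtype=float)
        if self.variable_names is None:
            self.variable_names = (
                ENV_VARIABLES[:n_vars]
                if n_vars <= len(ENV_VARIABLES)
                else [f"v{i + 1}" for i in range(n_vars)]
            )
        if len(self.variable_names) != n_vars:
            raise ValueError("one name per variable required")


def make_env_table(spec: FactorSpec) -> pd.DataFrame:
    """Draw observations from the factor model of ``spec``.

    Latent factors are iid standard normal; rows are
    ``loading_matrix @ f + unique_sd * eps``. With loadings completing to
    unit variance the population covariance is a correlation matrix
    ``L L' + diag(unique_sd^2)``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.loading_matrix
    n_vars, n_fac = L.shape
    f = rng.standard_normal((spec.n_obs, n_fac))
    eps = rng.standard_normal((spec.n_obs, n_vars)) * spec.unique_sd
    data = f @ L.T + eps
    return pd.DataFrame(data, columns=spec.variable_names)
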