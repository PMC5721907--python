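"""MaxEnt background/bias surface construction.

A bias surface restricts and weights where a presence-background model
draws its background (pseudo-absence) points: cells inside the sampled
region carry positive weights, cells outside are NoData.  Four
constructions are provided, from most to least inclusive:

* buffered minimum convex polygon (MCP) of the occurrences;
* buffered local adaptive convex hull — occurrences are clustered by
  single linkage at a distance ``alpha`` and each cluster contributes the
  buffer-dilation of its own convex hull, so the region is a union of
  disjunct buffered polygons.  As ``alpha`` grows it converges to the
  buffered MCP; as ``alpha`` shrinks, to the union of per-point disks;
* union of disks of a fixed radius around the occurrences;
* Gaussian kernel density of sampling localities (a graded weight rather
  than a uniform mask).

Region membership is evaluated per template cell center with exact
Euclidean point-to-hull distances, so the limit equivalences above hold
as exact cell-set equalities.  All surfaces are masked to the template's
data cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from shapely.geometry import MultiPoint

from .grids import Grid
from .occurrences import OccurrenceSet

__all__ = ["BiasSurface", "AlphaHullParams", "bias_buffered_mcp",
           "bias_distance", "bias_gaussian_kde", "bias_alpha_hull"]

#: KDE weights below this fraction of the maximum are excluded from the
#: background region entirely (MaxEnt bias must be positive where sampling
#: is allowed).
KDE_FLOOR = 1e-6


@dataclass
class BiasSurface:
    """Positive sampling weights on a template geometry; NoData elsewhere."""

    grid: Grid

    def __post_init__(self):
        data = self.grid.values[self.grid.data_mask()]
        if data.size and (data <= 0).any():
            raise ValueError("bias weights must be positive")

    def region_mask(self) -> np.ndarray:
        return self.grid.data_mask()

    def cell_count(self) -> int:
        return int(self.region_mask().sum())


@dataclass
class AlphaHullParams:
    """Parameters of the local adaptive convex hull."""

    alpha: float   # single-linkage aggregation distance, map units
    buffer: float  # hull dilation distance, map units

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.buffer < 0:
            raise ValueError("buffer must be >= 0")


def _require_points(occ: OccurrenceSet) -> np.ndarray:
    if len(occ) == 0:
        raise ValueError("empty occurrence set")
    return occ.coords()


def _mask_to_surface(template: Grid, inside: np.ndarray) -> BiasSurface:
    """Weight-1 surface over `inside & template data cells`."""
    vals = np.full(template.values.shape, template.nodata)
    region = inside & template.data_mask()
    vals[region] = 1.0
    return BiasSurface(template.like(vals))


def _within_hull_distance(template: Grid, hulls, buffer: float) -> np.ndarray:
    """Cells whose center lies within `buffer` of any hull geometry.

    ``hulls`` are shapely geometries (Point / LineString / Polygon — the
    convex hull of 1, 2-or-collinear, or >=3 points respectively), so the
    dilation of a polygon is tested exactly and degenerate hulls become
    disks and capsules without special-casing.
    """
    from shapely import distance as shp_distance
    from shapely import points as shp_points

    xs, ys = template.center_coords()
    centers = shp_points(np.column_stack([xs.ravel(), ys.ravel()]))
    inside = np.zeros(centers.shape[0], dtype=bool)
    for hull in hulls:
        inside |= shp_distance(centers, hull) <= buffer
    return inside.reshape(template.values.shape)


def bias_buffered_mcp(occ: OccurrenceSet, buffer: float, template: Grid) -> BiasSurface:
    """Buffered minimum convex polygon of the occurrences, weight 1 inside.

    Degenerate inputs follow the hull's own geometry: a single point gives
    a disk of radius ``buffer``, two points or collinear points a capsule.
    """
    pts = _require_points(occ)
    hull = MultiPoint(pts).convex_hull
    inside = _within_hull_distance(template, [hull], buffer)
    return _mask_to_surface(template, inside)


def bias_distance(occ: OccurrenceSet, radius: float, template: Grid) -> BiasSurface:
    """Union of disks of ``radius`` around the occurrences, weight 1 inside."""
    from shapely.geometry import Point

    if radius < 0:
        raise ValueError("radius must be >= 0")
    pts = _require_points(occ)
    # same exact-distance predicate as the hull-based surfaces, so the
    # small-alpha limit of the alpha hull matches this region cell-for-cell
    inside = _within_hull_distance(template, [Point(p) for p in pts], radius)
    if radius == 0:
        # half-open cell ownership: a point owns its containing cell even
        # when it is not exactly at the center
        for x, y in pts:
            idx = template.index_of(x, y)
            if idx is not None:
                inside[idx] = True
    return _mask_to_surface(template, inside)


def bias_gaussian_kde(occ: OccurrenceSet, bandwidth: float, template: Grid,
                      floor: float = KDE_FLOOR) -> BiasSurface:
    """Gaussian kernel density of sampling localities.

    Cell weight is ``sum_i exp(-d_i^2 / (2 h^2))`` over occurrences,
    rescaled so the maximum is 1.  Cells below ``floor`` (relative to the
    maximum) are excluded from the background region rather than carrying
    a vanishing weight.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    pts = _require_points(occ)
    xs, ys = template.center_coords()
    d2 = ((xs[..., None] - pts[:, 0]) ** 2 + (ys[..., None] - pts[:, 1]) ** 2)
    dens = np.exp(-d2 / (2.0 * bandwidth ** 2)).sum(axis=-1)
    mask = template.data_mask()
    peak = dens[mask].max() if mask.any() else dens.max()
    dens = dens / peak
    vals = np.full(template.values.shape, template.nodata)
    region = mask & (dens >= floor)
    vals[region] = dens[region]
    return BiasSurface(template.like(vals))


def cluster_points(pts: np.ndarray, alpha: float) -> np.ndarray:
    """Single-linkage cluster labels at aggregation distance ``alpha``.

    Two points share a cluster iff a chain of pairwise steps < ``alpha``
    connects them (strict, so ``alpha`` below the minimum pairwise distance
    leaves every point a singleton, matching the distance-surface limit).
    """
    n = len(pts)
    if n == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(pts, method="single")
    # fcluster criterion 'distance' merges at <= t; shrink t marginally so
    # the threshold behaves strictly (< alpha)
    t = np.nextafter(alpha, 0.0)
    return fcluster(Z, t=t, criterion="distance") - 1


def bias_alpha_hull(occ: OccurrenceSet, params: AlphaHullParams,
                    template: Grid) -> BiasSurface:
    """Buffered local adaptive convex hull.

    Occurrences are aggregated by single linkage at ``params.alpha``; each
    cluster contributes the ``params.buffer``-dilation of its convex hull
    (disk for singletons, capsule for 2-point or collinear clusters).  The
    region is the union over clusters, weight 1 inside.
    """
    pts = _require_points(occ)
    labels = cluster_points(pts, params.alpha)
    hulls = [MultiPoint(pts[labels == k]).convex_hull
             for k in np.unique(labels)]
    inside = _within_hull_distance(template, hulls, params.buffer)
    if params.buffer == 0:
        for x, y in pts:
            idx = template.index_of(x, y)
            if idx is not None:
                inside[idx] = True
    return _mask_to_surface(template, inside)
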