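"""Seeded synthetic-data generators.

Every scenario the toolkit operates on can be generated here with no
download: smooth/patchy environmental gradients, clustered occurrence
point sets, binary range stacks, cost surfaces with walls and gaps, and
randomization tables with planted endemism categories.  All generators
are deterministic under ``FixtureSpec.seed``.

These fixtures emulate the *shape* of real inputs (spatial clustering,
gradients, NoData borders, rank-p tables), not their ecology: gradients
are noiseless monotone fields and cluster memberships are exact, so tests
passing here demonstrate algorithmic correctness, not predictive skill on
real species data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .biodiversity import (CANAPE_CATEGORIES, BinaryStack, CanapeThresholds,
                           DEFAULT_COLUMNS, RandomizationTable)
from .connectivity import CostSurface
from .grids import ExtentSpec, Grid
from .occurrences import OccurrenceRecord, OccurrenceSet

__all__ = ["FixtureSpec", "make_landscape", "make_occurrences",
           "make_binary_stack", "make_cost_surface",
           "make_randomization_table"]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic scenarios."""

    seed: int = 0
    extent: ExtentSpec = field(default_factory=lambda: ExtentSpec(0, 0, 100, 100))
    cellsize: float = 1.0
    nodata: float = -9999.0
    # landscape
    gradient_axis: str = "x"        # direction of monotone increase
    patch_scale: float = 5.0        # smoothing radius of the patchy layer, cells
    nodata_border: int = 0          # NoData frame width, cells
    # occurrences
    n_clusters: int = 3
    points_per_cluster: int = 10
    cluster_spread: float = 3.0     # Gaussian sd around each center, map units
    cluster_centers: list[tuple[float, float]] | None = None
    label_clusters: bool = False    # tag each cluster as a clade
    species: str = "sp1"
    # cost surface
    wall_cost: float = 100.0
    wall_gap_row: int | None = None

    @property
    def nrows(self) -> int:
        return round((self.extent.ymax - self.extent.ymin) / self.cellsize)

    @property
    def ncols(self) -> int:
        return round((self.extent.xmax - self.extent.xmin) / self.cellsize)

    def template(self) -> Grid:
        vals = np.zeros((self.nrows, self.ncols))
        return Grid(vals, self.extent.xmin, self.extent.ymin, self.cellsize,
                    self.nodata)

    def default_centers(self) -> list[tuple[float, float]]:
        """Cluster centers spread along the gradient axis (so spatially
        segregated groups also differ environmentally)."""
        if self.cluster_centers is not None:
            return list(self.cluster_centers)
        ex = self.extent
        w, h = ex.xmax - ex.xmin, ex.ymax - ex.ymin
        fracs = np.linspace(0.15, 0.85, self.n_clusters)
        ys = [0.3, 0.7]
        out = []
        for i, f in enumerate(fracs):
            if self.gradient_axis == "x":
                out.append((ex.xmin + f * w, ex.ymin + ys[i % 2] * h))
            else:
                out.append((ex.xmin + ys[i % 2] * w, ex.ymin + f * h))
        return out


def _apply_border(vals: np.ndarray, spec: FixtureSpec) -> None:
    b = spec.nodata_border
    if b > 0:
        vals[:b, :] = spec.nodata
        vals[-b:, :] = spec.nodata
        vals[:, :b] = spec.nodata
        vals[:, -b:] = spec.nodata


def make_landscape(spec: FixtureSpec) -> dict[str, Grid]:
    """Two-layer environmental stack: a strict monotone gradient and a
    smooth patchy field, with an optional NoData border."""
    tpl = spec.template()
    xs, ys = tpl.center_coords()
    grad = xs.copy() if spec.gradient_axis == "x" else ys.copy()
    rng = np.random.default_rng(spec.seed)
    noise = rng.uniform(0.0, 1.0, size=(spec.nrows, spec.ncols))
    patchy = gaussian_filter(noise, sigma=spec.patch_scale)
    _apply_border(grad, spec)
    _apply_border(patchy, spec)
    return {"gradient": tpl.like(grad), "patchy": tpl.like(patchy)}


def make_occurrences(spec: FixtureSpec) -> OccurrenceSet:
    """Gaussian occurrence clusters, optionally clade-labelled per cluster.

    Points are clipped back into the extent (reflecting real datasets that
    never leave the study region) by resampling stray draws.
    """
    rng = np.random.default_rng(spec.seed)
    ex = spec.extent
    records = []
    for ci, (cx, cy) in enumerate(spec.default_centers()):
        label = f"clade_{ci}" if spec.label_clusters else None
        made = 0
        while made < spec.points_per_cluster:
            x = rng.normal(cx, spec.cluster_spread) if spec.cluster_spread > 0 else cx
            y = rng.normal(cy, spec.cluster_spread) if spec.cluster_spread > 0 else cy
            if ex.xmin <= x < ex.xmax and ex.ymin <= y < ex.ymax:
                records.append(OccurrenceRecord(spec.species, x, y, label))
                made += 1
    return OccurrenceSet(records)


def make_binary_stack(spec: FixtureSpec, n_species: int = 4,
                      radius_range: tuple[float, float] = (5.0, 20.0)
                      ) -> BinaryStack:
    """Binary range grids: each species occupies a disk of seeded center
    and radius (ranges overlap, sizes vary, so WE/CWE are non-trivial)."""
    rng = np.random.default_rng(spec.seed)
    tpl = spec.template()
    xs, ys = tpl.center_coords()
    ex = spec.extent
    grids = {}
    for i in range(n_species):
        cx = rng.uniform(ex.xmin, ex.xmax)
        cy = rng.uniform(ex.ymin, ex.ymax)
        r = rng.uniform(*radius_range)
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
        if not inside.any():  # guarantee a non-empty range
            inside[tpl.index_of(cx, cy) or (0, 0)] = True
        grids[f"sp{i + 1}"] = tpl.like(inside.astype(float))
    return BinaryStack(grids)


def make_cost_surface(spec: FixtureSpec) -> CostSurface:
    """Uniform unit-cost surface with a high-cost vertical wall pierced by
    a single-cell gap (classic LCP routing scenario)."""
    vals = np.ones((spec.nrows, spec.ncols))
    wall_col = spec.ncols // 2
    gap = spec.wall_gap_row if spec.wall_gap_row is not None else spec.nrows // 2
    vals[:, wall_col] = spec.wall_cost
    vals[gap, wall_col] = 1.0
    _apply_border(vals, spec)
    return CostSurface(Grid(vals, spec.extent.xmin, spec.extent.ymin,
                            spec.cellsize, spec.nodata))


# category -> safe rank-p sampling ranges (p_pe_orig, p_pe_comp, p_rpe)
# under the default CANAPE thresholds; each range keeps the planted
# category unambiguous
def _category_ranges(thr: CanapeThresholds):
    eps = 1e-3
    mid = (thr.neo + eps, thr.paleo - eps)
    return {
        "non-significant": ((0.05, thr.significant - eps),
                            (0.05, thr.significant - eps), (0.0, 1.0)),
        "neo": ((thr.significant, thr.super_ - eps), (0.0, thr.significant - eps),
                (0.0, thr.neo)),
        "paleo": ((thr.significant, thr.super_ - eps), (0.0, thr.significant - eps),
                  (thr.paleo, 1.0)),
        "mixed": ((thr.significant, thr.super_ - eps), (0.0, thr.significant - eps),
                  mid),
        "super": ((thr.super_, 1.0), (thr.super_, 1.0), (0.0, 1.0)),
    }


def make_randomization_table(spec: FixtureSpec,
                             planted: list[str] | None = None,
                             n_cells: int = 50,
                             thresholds: CanapeThresholds | None = None
                             ) -> tuple[RandomizationTable, list[str]]:
    """Randomization export with planted CANAPE categories.

    Rank-p fields are drawn uniformly inside ranges consistent with each
    planted category under the given thresholds, so classification must
    recover the planted labels exactly.  Returns (table, planted labels).
    """
    thr = thresholds or CanapeThresholds()
    rng = np.random.default_rng(spec.seed)
    tpl = spec.template()
    if planted is None:
        planted = [CANAPE_CATEGORIES[rng.integers(len(CANAPE_CATEGORIES))]
                   for _ in range(n_cells)]
    n = len(planted)
    if n > tpl.nrows * tpl.ncols:
        raise ValueError("more planted cells than template cells")
    flat = rng.choice(tpl.nrows * tpl.ncols, size=n, replace=False)
    ranges = _category_ranges(thr)
    rows = []
    for cell, cat in zip(flat, planted):
        r, c = divmod(int(cell), tpl.ncols)
        x, y = tpl.cell_center(r, c)
        (o_lo, o_hi), (c_lo, c_hi), (r_lo, r_hi) = ranges[cat]
        rows.append({
            DEFAULT_COLUMNS["x"]: x,
            DEFAULT_COLUMNS["y"]: y,
            DEFAULT_COLUMNS["p_pe_orig"]: rng.uniform(o_lo, o_hi),
            DEFAULT_COLUMNS["p_pe_comp"]: rng.uniform(c_lo, c_hi),
            DEFAULT_COLUMNS["p_rpe"]: rng.uniform(r_lo, r_hi),
        })
    return RandomizationTable(pd.DataFrame(rows)), list(planted)
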