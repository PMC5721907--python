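"""Cost-distance surfaces, least-cost paths, corridors, pairwise matrices.

The landscape is an 8-connected lattice over a positive per-cell cost
(friction) raster; NoData cells are impassable.  Moving between adjacent
cells costs ``steplength * (cost_a + cost_b) / 2``, where steplength is
the cellsize for cardinal moves and cellsize * sqrt(2) for diagonal moves
— the ubiquitous GIS cost-distance convention.  A least-cost path (LCP)
minimises the accumulated cost; a corridor between two sites is the
cellwise sum of their two cost-distance surfaces, whose minimum equals
the LCP cost and is attained on every LCP cell.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .grids import Grid

__all__ = ["CostSurface", "PathResult", "UNREACHABLE", "cost_distance",
           "least_cost_path", "pairwise_matrices", "corridor"]

#: sentinel for unreachable pairs in distance matrices
UNREACHABLE = np.inf

# move order defines the deterministic tie-break (lexicographically
# smallest move sequence): N, NE, E, SE, S, SW, W, NW
_MOVES = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass
class CostSurface:
    """Positive per-cell traversal costs; NoData = impassable."""

    grid: Grid

    def __post_init__(self):
        data = self.grid.values[self.grid.data_mask()]
        if data.size and (data <= 0).any():
            raise ValueError("traversal costs must be positive")

    def passable(self) -> np.ndarray:
        return self.grid.data_mask()

    def snap(self, point) -> tuple[int, int]:
        """Containing cell of a point; raises if outside or impassable."""
        idx = self.grid.index_of(*point)
        if idx is None:
            raise ValueError(f"point {point} lies outside the cost surface")
        if not self.passable()[idx]:
            raise ValueError(f"point {point} falls on an impassable cell")
        return idx


@dataclass
class PathResult:
    """An LCP as a cell-center polyline with its two lengths."""

    cells: list[tuple[int, int]]          # (row, col) sequence, 8-adjacent
    coords: list[tuple[float, float]]     # cell-center polyline
    cost: float                           # accumulated traversal cost
    length: float                         # geographic length, map units

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.cost)


def _edge_weight(cost: CostSurface, a: tuple[int, int], b: tuple[int, int]) -> float:
    cs = cost.grid.cellsize
    step = cs * math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else cs
    return step * (cost.grid.values[a] + cost.grid.values[b]) / 2.0


def _build_graph(cost: CostSurface):
    """Sparse 8-connectivity graph over passable cells.

    Returns (csr matrix over flat passable-node ids, flat index array
    mapping grid cell -> node id or -1).
    """
    g = cost.grid
    passable = cost.passable()
    node = np.full(g.values.shape, -1, dtype=int)
    rr, cc = np.nonzero(passable)
    node[rr, cc] = np.arange(rr.size)
    rows, cols, data = [], [], []
    cs = g.cellsize
    for dr, dc in ((-1, 0), (0, 1), (-1, 1), (1, 1)):  # each edge once
        step = cs * math.sqrt(2.0) if (dr and dc) else cs
        r2, c2 = rr + dr, cc + dc
        ok = (0 <= r2) & (r2 < g.nrows) & (0 <= c2) & (c2 < g.ncols)
        ok[ok] &= passable[r2[ok], c2[ok]]
        w = step * (g.values[rr[ok], cc[ok]] + g.values[r2[ok], c2[ok]]) / 2.0
        rows.extend(node[rr[ok], cc[ok]])
        cols.extend(node[r2[ok], c2[ok]])
        data.extend(w)
    n = rr.size
    mat = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return mat, node


def cost_distance(cost: CostSurface, sources) -> Grid:
    """Minimal accumulated cost from any source point to every cell.

    Unreachable (or impassable) cells are NoData.
    """
    src_cells = [cost.snap(p) for p in np.atleast_2d(np.asarray(sources, dtype=float))]
    mat, node = _build_graph(cost)
    src_ids = sorted({node[c] for c in src_cells})
    dist = _csgraph_dijkstra(mat, directed=False, indices=src_ids, min_only=True)
    g = cost.grid
    out = np.full(g.values.shape, g.nodata)
    passable = cost.passable()
    vals = dist[node[passable]]
    vals = np.where(np.isfinite(vals), vals, g.nodata)
    out[passable] = vals
    return g.like(out)


def least_cost_path(cost: CostSurface, a, b) -> PathResult:
    """Deterministic least-cost path between two points.

    Dijkstra over the 8-connected lattice; among equal-cost paths the one
    with fewer steps wins, then the lexicographically smallest move
    sequence (moves ordered N, NE, E, SE, S, SW, W, NW).  A disconnected
    pair yields an explicit unreachable result (infinite cost, no cells).
    """
    start = cost.snap(a)
    goal = cost.snap(b)
    g = cost.grid
    if start == goal:
        return PathResult([start], [g.cell_center(*start)], 0.0, 0.0)
    passable = cost.passable()
    # heap entries: (cost, steps, moves, cell); moves compared only on ties
    heap = [(0.0, 0, (), start)]
    settled: set[tuple[int, int]] = set()
    best: dict[tuple[int, int], tuple[float, int, tuple]] = {start: (0.0, 0, ())}
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    while heap:
        d, steps, moves, cell = heapq.heappop(heap)
        if cell in settled:
            continue
        settled.add(cell)
        if cell == goal:
            break
        for mi, (dr, dc) in enumerate(_MOVES):
            nb = (cell[0] + dr, cell[1] + dc)
            if not (0 <= nb[0] < g.nrows and 0 <= nb[1] < g.ncols):
                continue
            if not passable[nb] or nb in settled:
                continue
            nd = d + _edge_weight(cost, cell, nb)
            key = (nd, steps + 1, moves + (mi,))
            if nb not in best or key < best[nb]:
                best[nb] = key
                parent[nb] = cell
                heapq.heappush(heap, (nd, steps + 1, moves + (mi,), nb))
    if goal not in settled:
        return PathResult([], [], math.inf, math.inf)
    cells = [goal]
    while cells[-1] != start:
        cells.append(parent[cells[-1]])
    cells.reverse()
    coords = [g.cell_center(r, c) for r, c in cells]
    length = sum(math.hypot(x2 - x1, y2 - y1)
                 for (x1, y1), (x2, y2) in zip(coords, coords[1:]))
    total = best[goal][0]
    return PathResult(cells, coords, float(total), float(length))


def pairwise_matrices(cost: CostSurface, points) -> tuple[np.ndarray, np.ndarray]:
    """n x n along-path-cost and LCP-geographic-length matrices.

    Symmetric with zero diagonal; unreachable pairs carry the
    :data:`UNREACHABLE` sentinel (infinity) in both matrices.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two sites")
    costs = np.zeros((n, n))
    lengths = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = least_cost_path(cost, pts[i], pts[j])
            c = res.cost if res.reachable else UNREACHABLE
            l = res.length if res.reachable else UNREACHABLE
            costs[i, j] = costs[j, i] = c
            lengths[i, j] = lengths[j, i] = l
    return costs, lengths


def corridor(cost: CostSurface, a, b, excess: bool = False) -> Grid:
    """Least-cost corridor surface between two points.

    Cellwise sum of the two cost-distance surfaces from ``a`` and ``b``:
    a cell's value is the cost of the cheapest a-to-b path constrained to
    pass through it, so the minimum over the corridor equals the LCP cost
    and is attained on every LCP cell.  With ``excess=True`` the minimum
    is subtracted, giving 0 along optimal paths.
    """
    da = cost_distance(cost, [a])
    db = cost_distance(cost, [b])
    g = cost.grid
    out = np.full(g.values.shape, g.nodata)
    ok = da.data_mask() & db.data_mask()
    out[ok] = da.values[ok] + db.values[ok]
    if not ok.any():
        raise ValueError("the two sites are mutually unreachable")
    if excess:
        out[ok] -= out[ok].min()
    return g.like(out)
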