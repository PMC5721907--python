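"""Raster data model and batch raster utilities.

The :class:`Grid` is the universal substrate of the toolkit: a rectangular
lattice of square cells in planar (projected) map units, with a lower-left
origin, a NoData sentinel, and values stored north-to-south (row 0 is the
northernmost row).  ESRI ASCII is the canonical text interchange format
(it is what MaxEnt consumes); a thin GeoTIFF adapter is provided on top of
tifffile.

Cell ownership follows the half-open convention
``[x0, x0 + cellsize) x [y0, y0 + cellsize)``: a point lying exactly on a
shared vertical edge belongs to the cell to its east, and a point on a
shared horizontal edge belongs to the cell to its north.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Grid",
    "ExtentSpec",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_esri_ascii_file",
    "write_esri_ascii_file",
    "read_geotiff",
    "write_geotiff",
    "upscale",
    "snap_extent",
    "redefine_nodata",
    "clip",
    "extract_values",
]

#: relative tolerance for lattice-alignment checks
_ALIGN_RTOL = 1e-9


@dataclass
class ExtentSpec:
    """Axis-aligned rectangle in map units."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("extent must satisfy xmin < xmax and ymin < ymax")


@dataclass
class Grid:
    """Rectangular raster lattice.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 northernmost.  Every entry is finite or equals
        ``nodata``.
    xll, yll : float
        Map coordinates of the outer lower-left corner.
    cellsize : float
        Side length of the (square) cells, in map units.
    nodata : float
        Sentinel marking missing cells.
    crs : str or None
        Opaque coordinate-reference tag carried through I/O, never
        interpreted.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0
    crs: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        bad = ~np.isfinite(self.values) & ~(self.values == self.nodata)
        if bad.any():
            raise ValueError("values must be finite or equal to the nodata sentinel")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> ExtentSpec:
        return ExtentSpec(
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def x_centers(self) -> np.ndarray:
        """Cell-center x coordinates, west to east."""
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates ordered like the rows (north to south)."""
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.xll + (col + 0.5) * self.cellsize
        y = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return x, y

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-center (x, y), each shaped like ``values``."""
        xs, ys = np.meshgrid(self.x_centers(), self.y_centers())
        return xs, ys

    def index_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/col of the cell owning (x, y), or None if outside the extent.

        Ownership is half-open: the west and south edges of a cell belong
        to it, the east and north edges to its neighbours.
        """
        col = math.floor((x - self.xll) / self.cellsize)
        row_s = math.floor((y - self.yll) / self.cellsize)  # from the south
        if not (0 <= col < self.ncols and 0 <= row_s < self.nrows):
            return None
        return self.nrows - 1 - row_s, col

    # -- masks ------------------------------------------------------------
    def data_mask(self) -> np.ndarray:
        """Boolean mask of cells holding data (not NoData)."""
        return self.values != self.nodata

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New grid on this grid's geometry with different values."""
        return Grid(
            np.asarray(values, dtype=float),
            self.xll,
            self.yll,
            self.cellsize,
            self.nodata if nodata is None else nodata,
            crs=self.crs,
        )

    def same_geometry(self, other: "Grid", rtol: float = _ALIGN_RTOL) -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.xll, other.xll, rel_tol=rtol, abs_tol=rtol)
            and math.isclose(self.yll, other.yll, rel_tol=rtol, abs_tol=rtol)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=rtol)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.same_geometry(other)
            and self.nodata == other.nodata
            and bool(np.array_equal(self.values, other.values))
        )


# ---------------------------------------------------------------------------
# ESRI ASCII I/O
# ---------------------------------------------------------------------------


def read_esri_ascii(text: str) -> Grid:
    """Parse an ESRI ASCII grid.

    Both ``xllcorner``/``yllcorner`` and ``xllcenter``/``yllcenter``
    headers are accepted; center-convention origins are normalised to the
    corner convention (corner = center - cellsize / 2).
    """
    stream = io.StringIO(text)
    header: dict[str, float] = {}
    keys = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner", "yllcenter",
            "cellsize", "nodata_value"}
    pos = stream.tell()
    for _ in range(6):
        line = stream.readline()
        parts = line.split()
        if len(parts) != 2 or parts[0].lower() not in keys:
            raise ValueError(f"malformed ESRI ASCII header line: {line!r}")
        header[parts[0].lower()] = float(parts[1])
        pos = stream.tell()
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"ESRI ASCII header missing {req}")
    if "nodata_value" not in header:
        raise ValueError("ESRI ASCII header missing NODATA_value")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2.0
    else:
        raise ValueError("ESRI ASCII header missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2.0
    else:
        raise ValueError("ESRI ASCII header missing yllcorner/yllcenter")
    stream.seek(pos)
    flat = np.array(stream.read().split(), dtype=float)
    if flat.size != nrows * ncols:
        raise ValueError(
            f"expected {nrows * ncols} values, found {flat.size}"
        )
    return Grid(flat.reshape(nrows, ncols), xll, yll, cellsize,
                header["nodata_value"])


def write_esri_ascii(grid: Grid, precision: int = 17) -> str:
    """Serialise a grid as ESRI ASCII text (corner-convention header).

    Values are written row-major, north to south, with enough digits
    (``precision`` significant figures) for a bit-faithful roundtrip of
    typical data.
    """
    fmt = f"%.{precision}g"
    lines = [
        f"ncols {grid.ncols}",
        f"nrows {grid.nrows}",
        "xllcorner " + (fmt % grid.xll),
        "yllcorner " + (fmt % grid.yll),
        "cellsize " + (fmt % grid.cellsize),
        "NODATA_value " + (fmt % grid.nodata),
    ]
    for row in grid.values:
        lines.append(" ".join(fmt % v for v in row))
    return "\n".join(lines) + "\n"


def read_esri_ascii_file(path) -> Grid:
    with open(path) as fh:
        return read_esri_ascii(fh.read())


def write_esri_ascii_file(grid: Grid, path, precision: int = 17) -> None:
    with open(path, "w") as fh:
        fh.write(write_esri_ascii(grid, precision=precision))


# ---------------------------------------------------------------------------
# GeoTIFF adapter (tifffile-backed; CRS is an opaque tag)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_GEO_ASCII = 34737


def write_geotiff(grid: Grid, path) -> None:
    """Write the grid as a single-band float GeoTIFF.

    The geotransform is stored via ModelPixelScale + ModelTiepoint, NoData
    via the GDAL_NODATA ascii tag, and any ``crs`` string verbatim in the
    GeoAsciiParams tag.  Nothing geodetic is computed.
    """
    import tifffile

    ytop = grid.yll + grid.nrows * grid.cellsize
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cellsize, grid.cellsize, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.xll, ytop, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    if grid.crs:
        extratags.append((_TAG_GEO_ASCII, "s", 0, grid.crs))
    tifffile.imwrite(path, grid.values.astype(np.float64), extratags=extratags)


def read_geotiff(path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise ValueError("TIFF lacks georeferencing tags") from exc
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError("non-square pixels are not supported")
        xll = tie[3]
        ytop = tie[4]
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        crs = None
        if _TAG_GEO_ASCII in tags:
            crs = str(tags[_TAG_GEO_ASCII].value).rstrip("\x00|") or None
    nrows = values.shape[0]
    yll = ytop - nrows * sx
    return Grid(values, xll, yll, sx, nodata, crs=crs)


# ---------------------------------------------------------------------------
# Raster utilities
# ---------------------------------------------------------------------------

_STATS = ("mean", "median", "majority", "minority", "min", "max", "sum")


def _block_stat(block: np.ndarray, nodata: float, stat: str) -> float:
    valid = block[block != nodata]
    if valid.size == 0:
        return nodata
    if stat == "mean":
        return float(valid.mean())
    if stat == "median":
        return float(np.median(valid))
    if stat == "min":
        return float(valid.min())
    if stat == "max":
        return float(valid.max())
    if stat == "sum":
        return float(valid.sum())
    # majority / minority: mode by count, ties broken by smallest value
    vals, counts = np.unique(valid, return_counts=True)
    if stat == "majority":
        return float(vals[np.argmax(counts)])  # argmax -> first (smallest) on tie
    return float(vals[np.argmin(counts)])


def upscale(grid: Grid, factor: int, stat: str = "mean") -> Grid:
    """Aggregate to a coarser resolution (cellsize scaled by ``factor``).

    Each output cell summarises its ``factor x factor`` block with ``stat``,
    ignoring NoData.  An all-NoData block stays NoData.  When ``factor``
    does not divide the dimensions, trailing partial blocks (on the east
    and south edges; blocks are tiled from the north-west corner) are
    aggregated over whatever valid cells they contain rather than dropped,
    and ``yll`` is recomputed so the north-west corner stays anchored.
    Majority/minority ties break toward the smallest value.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if stat not in _STATS:
        raise ValueError(f"unknown stat {stat!r}; expected one of {_STATS}")
    if factor == 1:
        return grid.copy()
    out_rows = math.ceil(grid.nrows / factor)
    out_cols = math.ceil(grid.ncols / factor)
    out = np.empty((out_rows, out_cols))
    for i in range(out_rows):
        for j in range(out_cols):
            block = grid.values[i * factor:(i + 1) * factor,
                                j * factor:(j + 1) * factor]
            out[i, j] = _block_stat(block, grid.nodata, stat)
    new_cs = grid.cellsize * factor
    ytop = grid.yll + grid.nrows * grid.cellsize
    return Grid(out, grid.xll, ytop - out_rows * new_cs, new_cs, grid.nodata,
                crs=grid.crs)


def _aligned_steps(value: float, origin: float, cellsize: float) -> int:
    steps = (value - origin) / cellsize
    rounded = round(steps)
    if abs(steps - rounded) > 1e-6:
        raise ValueError(
            f"coordinate {value} is not aligned to the lattice "
            f"(origin {origin}, cellsize {cellsize})"
        )
    return int(rounded)


def snap_extent(grids: list[Grid], target: ExtentSpec) -> list[Grid]:
    """Grow/shrink every grid to a common, lattice-aligned target extent.

    Added cells are filled with each grid's NoData sentinel; surviving data
    values are never altered.  All grids must share a cellsize and the
    target edges must sit on the shared lattice.
    """
    if not grids:
        return []
    cs = grids[0].cellsize
    for g in grids[1:]:
        if not math.isclose(g.cellsize, cs, rel_tol=_ALIGN_RTOL):
            raise ValueError("all grids must share a cellsize")
    out = []
    for g in grids:
        left = _aligned_steps(target.xmin, g.xll, cs)
        bottom = _aligned_steps(target.ymin, g.yll, cs)
        right = _aligned_steps(target.xmax, g.xll, cs)
        top = _aligned_steps(target.ymax, g.yll, cs)
        ncols = right - left
        nrows = top - bottom
        vals = np.full((nrows, ncols), g.nodata)
        for r in range(nrows):
            src_r = r + (g.nrows - top)  # row in source counted from source top
            if not (0 <= src_r < g.nrows):
                continue
            c0 = max(0, -left)
            c1 = min(ncols, g.ncols - left)
            if c0 < c1:
                vals[r, c0:c1] = g.values[src_r, c0 + left:c1 + left]
        out.append(Grid(vals, g.xll + left * cs, g.yll + bottom * cs, cs,
                        g.nodata, crs=g.crs))
    return out


def redefine_nodata(grid: Grid, new_sentinel: float) -> Grid:
    """Swap the NoData sentinel; data cells are untouched.

    If any data cell already equals ``new_sentinel`` those cells become
    indistinguishable from NoData; a warning reporting the collision count
    is emitted.
    """
    collisions = int(np.sum((grid.values == new_sentinel)
                            & (grid.values != grid.nodata)))
    if collisions:
        warnings.warn(
            f"{collisions} data cell(s) already equal the new sentinel "
            f"{new_sentinel} and will be coerced to NoData",
            stacklevel=2,
        )
    vals = grid.values.copy()
    vals[vals == grid.nodata] = new_sentinel
    return Grid(vals, grid.xll, grid.yll, grid.cellsize, new_sentinel,
                crs=grid.crs)


def clip(grid: Grid, region) -> Grid:
    """Crop to an :class:`ExtentSpec` or a shapely polygon.

    The output extent is the lattice-aligned bounding box of the region
    intersected with the grid; for polygon regions, cells whose centers
    fall outside the polygon additionally become NoData.
    """
    from shapely.geometry import Point, Polygon

    polygon = None
    if isinstance(region, ExtentSpec):
        xmin, ymin, xmax, ymax = region.xmin, region.ymin, region.xmax, region.ymax
    elif isinstance(region, Polygon):
        polygon = region
        xmin, ymin, xmax, ymax = region.bounds
    else:
        raise TypeError("region must be an ExtentSpec or a shapely Polygon")
    cs = grid.cellsize
    ext = grid.extent
    # lattice-aligned bounding box, clamped to the grid
    left = max(0, math.floor((xmin - grid.xll) / cs))
    bottom = max(0, math.floor((ymin - grid.yll) / cs))
    right = min(grid.ncols, math.ceil((xmax - grid.xll) / cs))
    top = min(grid.nrows, math.ceil((ymax - grid.yll) / cs))
    if left >= right or bottom >= top:
        raise ValueError("region does not overlap the grid")
    r0 = grid.nrows - top
    r1 = grid.nrows - bottom
    vals = grid.values[r0:r1, left:right].copy()
    out = Grid(vals, grid.xll + left * cs, grid.yll + bottom * cs, cs,
               grid.nodata, crs=grid.crs)
    if polygon is not None:
        xs, ys = out.center_coords()
        outside = np.array(
            [not polygon.covers(Point(x, y))
             for x, y in zip(xs.ravel(), ys.ravel())]
        ).reshape(vals.shape)
        vals[outside] = out.nodata
    return out


def extract_values(grids: dict[str, Grid], occ) -> "pandas.DataFrame":
    """Sample named rasters at occurrence locations.

    Returns one row per occurrence with a column per grid.  Points outside
    the shared extent get flag ``"outside"`` and NaN values; points whose
    containing cell is NoData in any grid get flag ``"nodata"`` (the NaN is
    only in the offending columns).  Nothing is silently dropped.
    """
    import pandas as pd

    if len(occ) == 0:
        raise ValueError("empty occurrence set")
    names = list(grids)
    gs = [grids[n] for n in names]
    for g in gs[1:]:
        if not g.same_geometry(gs[0]):
            raise ValueError("all grids must share extent and cellsize")
    rows = []
    for rec in occ.records:
        row = {"species": rec.species, "x": rec.x, "y": rec.y}
        idx = gs[0].index_of(rec.x, rec.y)
        flag = "ok"
        if idx is None:
            flag = "outside"
            for n in names:
                row[n] = np.nan
        else:
            r, c = idx
            for n, g in zip(names, gs):
                v = g.values[r, c]
                if v == g.nodata:
                    row[n] = np.nan
                    flag = "nodata"
                else:
                    row[n] = v
        row["flag"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
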