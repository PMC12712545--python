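"""Shared raster data model, I/O, and class-break algorithms.

The :class:`Grid` is the single spatial container used throughout the
package: a 2-D value array, a nodata mask, a cell size in meters and a
top-left origin.  All layers in one analysis are assumed pre-aligned
(same shape, cell size and origin); no reprojection is performed.

Two classification algorithms live here because three downstream stages
share them: equal-interval breaks (habitat-quality levels) and exact
Fisher–Jenks natural breaks (carbon zones, suitability classes).
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger("gapscape")

#: Land-use legend shared across the package (codes 1..6).
LANDUSE_LEGEND = {
    1: "cropland",
    2: "woodland",
    3: "grassland",
    4: "water",
    5: "construction",
    6: "unused",
}

EQUAL_INTERVAL = "equal_interval"
JENKS = "jenks"


# ---------------------------------------------------------------------------
# Grid data model
# ---------------------------------------------------------------------------

@dataclass
class Grid:
    """A single-band, north-up raster.

    Parameters
    ----------
    values
        2-D array of cell values. Row 0 is the northernmost row.
    nodata_mask
        Boolean array of the same shape; True marks cells without data.
    cell_size_m
        Cell edge length in meters (square cells). Default 1000 m, i.e.
        one cell covers 1 km².
    origin
        (x, y) map coordinates of the top-left corner of the top-left cell.
    crs_label
        Free-text CRS description; carried through, never interpreted.
    """

    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    cell_size_m: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_area_km2 * 100.0

    def valid(self) -> np.ndarray:
        """Values at non-nodata cells, as a 1-D array."""
        return self.values[~self.nodata_mask]

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """A new grid with this grid's geometry and the given values."""
        return Grid(
            values=np.asarray(values),
            nodata_mask=self.nodata_mask.copy() if mask is None else np.asarray(mask, bool),
            cell_size_m=self.cell_size_m,
            origin=self.origin,
            crs_label=self.crs_label,
        )

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin, other.origin)
        )

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise ValueError(f"misaligned {what}: {self.shape} vs {other.shape}")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size_m, y0 - (row + 0.5) * self.cell_size_m)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size_m))
        row = int(np.floor((y0 - y) / self.cell_size_m))
        return row, col


@dataclass
class LandUseMap:
    """Categorical land-use raster over six broad classes."""

    grid: Grid
    legend: dict[int, str] = field(default_factory=lambda: dict(LANDUSE_LEGEND))

    def __post_init__(self) -> None:
        vals = self.grid.valid()
        codes = np.unique(vals.astype(int))
        bad = [int(c) for c in codes if c not in self.legend]
        if bad:
            raise ValueError(f"land-use codes outside legend: {bad}")

    @property
    def codes(self) -> list[int]:
        return sorted(self.legend)

    def mask_of(self, *class_names: str) -> Grid:
        """Boolean grid of cells whose class name is in ``class_names``."""
        wanted = {c for c, n in self.legend.items() if n in class_names}
        out = np.isin(self.grid.values, list(wanted)) & ~self.grid.nodata_mask
        return self.grid.like(out)


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid (primary, text) and single-band TIFF
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_grid(grid: Grid, path: str) -> None:
    """Write a grid to disk; format chosen by extension (.asc or .tif)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".txt"):
        _write_ascii(grid, path)
    elif ext in (".tif", ".tiff"):
        _write_tiff(grid, path)
    else:
        raise ValueError(f"unsupported raster extension: {path}")


def read_grid(path: str) -> Grid:
    """Read a single-band raster from .asc or .tif."""
    if not os.path.exists(path):
        raise IOError(f"unreadable raster file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".txt"):
        return _read_ascii(path)
    if ext in (".tif", ".tiff"):
        return _read_tiff(path)
    raise ValueError(f"unsupported raster extension: {path}")


def _write_ascii(grid: Grid, path: str) -> None:
    rows, cols = grid.shape
    x0, y0 = grid.origin
    yll = y0 - rows * grid.cell_size_m
    vals = np.array(grid.values, dtype=float)
    vals[grid.nodata_mask] = _NODATA
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    fmt = "%d" if is_int else "%.17g"
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size_m!r}\n"
        f"NODATA_value {int(_NODATA) if is_int else _NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals.astype(int) if is_int else vals, fmt=fmt)
    if grid.crs_label:
        with open(os.path.splitext(path)[0] + ".prj", "w") as fh:
            fh.write(grid.crs_label + "\n")


def _read_ascii(path: str) -> Grid:
    header: dict[str, float] = {}
    tokens: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2 or not line[0][0].isalpha():
                fh.seek(pos)
                break
            header[line[0].lower()] = float(line[1])
            tokens[line[0].lower()] = line[1]
            pos = fh.tell()
        try:
            data = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise IOError(f"unreadable raster file: {path}") from exc
    if {"ncols", "nrows", "cellsize"} - set(header):
        raise IOError(f"unreadable raster file (bad ASCII-grid header): {path}")
    nodata = header.get("nodata_value", _NODATA)
    mask = data == nodata
    # integer grids are written with an integer NODATA token; preserve dtype
    nd_tok = tokens.get("nodata_value", "")
    if nd_tok and not any(c in nd_tok for c in ".eE") and np.array_equal(
            data, np.round(data)):
        data = data.astype(np.int64)
    cell = header["cellsize"]
    y0 = header.get("yllcorner", 0.0) + header["nrows"] * cell
    crs = ""
    prj = os.path.splitext(path)[0] + ".prj"
    if os.path.exists(prj):
        with open(prj) as fh:
            crs = fh.read().strip()
    return Grid(values=data, nodata_mask=mask, cell_size_m=cell,
                origin=(header.get("xllcorner", 0.0), y0), crs_label=crs)


def _write_tiff(grid: Grid, path: str) -> None:
    import tifffile

    vals = np.array(grid.values, dtype=grid.values.dtype)
    if np.issubdtype(vals.dtype, np.floating):
        vals = vals.astype(np.float64)
        vals[grid.nodata_mask] = _NODATA
    else:
        vals = vals.astype(np.int32)
        vals[grid.nodata_mask] = int(_NODATA)
    x0, y0 = grid.origin
    c = float(grid.cell_size_m)
    extratags = [
        # GeoTIFF ModelPixelScale and ModelTiepoint
        (33550, "d", 3, (c, c, 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (34737, "s", 0, grid.crs_label or " "),  # GeoAsciiParams carries CRS text
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def _read_tiff(path: str) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) > 1:
            raise ValueError(f"single band required: {path} has {len(tf.pages)} pages")
        page = tf.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"single band required: {path} has shape {data.shape}")
        tags = page.tags
        cell = 1000.0
        origin = (0.0, 0.0)
        crs = ""
        if 33550 in tags:
            cell = float(tags[33550].value[0])
        if 33922 in tags:
            tp = tags[33922].value
            origin = (float(tp[3]), float(tp[4]))
        if 34737 in tags:
            crs = str(tags[34737].value).strip()
    mask = data == (_NODATA if np.issubdtype(data.dtype, np.floating) else int(_NODATA))
    return Grid(values=data, nodata_mask=mask, cell_size_m=cell, origin=origin,
                crs_label=crs)


# ---------------------------------------------------------------------------
# Class breaks
# ---------------------------------------------------------------------------

@dataclass
class ClassBreaks:
    """k classes delimited by k+1 ascending edges."""

    edges: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or len(self.edges) < 2:
            raise ValueError("need at least 2 edges")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly ascending")

    @property
    def k(self) -> int:
        return len(self.edges) - 1

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"method": self.method,
                            "edges": [float(e) for e in self.edges]}, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "ClassBreaks":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(edges=np.asarray(d["edges"]), method=d["method"])


def equal_interval_breaks(values, k: int, bounds: tuple[float, float] | None = None
                          ) -> ClassBreaks:
    """Equal-interval breaks over the data range (or fixed ``bounds``).

    With ``bounds=(0, 1)`` and ``k=5`` the edges are exactly
    0, 0.2, 0.4, 0.6, 0.8, 1 — the conventional five habitat-quality
    levels (low, moderately low, medium, moderately high, high).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if bounds is not None:
        lo, hi = float(bounds[0]), float(bounds[1])
    else:
        arr = np.asarray(values, dtype=float).ravel()
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError("no finite values to classify")
        lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn("degenerate range (max == min): single class")
        return ClassBreaks(edges=np.array([lo, lo + 1.0]), method=EQUAL_INTERVAL)
    edges = lo + np.arange(k + 1) * (hi - lo) / k
    edges[-1] = hi  # guard accumulation error at the top edge
    return ClassBreaks(edges=edges, method=EQUAL_INTERVAL)


def _weighted_jenks_partition(vals: np.ndarray, wts: np.ndarray, k: int
                              ) -> list[int]:
    """Optimal contiguous partition of weighted sorted values, O(k·m²) DP.

    Returns the list of group start indices (length k). Exact
    Fisher-style dynamic programming, deterministic.
    """
    m = len(vals)
    cw = np.concatenate([[0.0], np.cumsum(wts)])
    cwx = np.concatenate([[0.0], np.cumsum(wts * vals)])
    cwx2 = np.concatenate([[0.0], np.cumsum(wts * vals * vals)])

    def ssq(i: int, j: int) -> float:
        # within-group SSQ for vals[i:j]
        w = cw[j] - cw[i]
        s = cwx[j] - cwx[i]
        s2 = cwx2[j] - cwx2[i]
        return max(0.0, s2 - s * s / w)

    INF = float("inf")
    cost = np.full((k + 1, m + 1), INF)
    back = np.zeros((k + 1, m + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, m + 1):
            best, arg = INF, g - 1
            for i in range(g - 1, j):
                c = cost[g - 1, i] + ssq(i, j)
                if c < best:
                    best, arg = c, i
            cost[g, j] = best
            back[g, j] = arg
    starts = []
    j = m
    for g in range(k, 0, -1):
        i = back[g, j]
        starts.append(i)
        j = i
    return starts[::-1]


def jenks_breaks(values, k: int) -> ClassBreaks:
    """Exact Fisher–Jenks natural breaks minimizing within-class SSQ.

    The DP runs on distinct values weighted by multiplicity, so ties are
    never split across classes; the optimum over class SSQ is unchanged.
    Interior edges are midpoints between adjacent distinct values of
    neighbouring classes, so edges are strictly ascending and each value
    classifies into its own class under the half-open convention.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite values")
    uvals, counts = np.unique(arr, return_counts=True)
    if len(uvals) < k:
        raise ValueError(
            f"need at least k={k} distinct values, got {len(uvals)}")
    starts = _weighted_jenks_partition(uvals, counts.astype(float), k)
    edges = [uvals[0]]
    for s in starts[1:]:
        edges.append(0.5 * (uvals[s - 1] + uvals[s]))
    edges.append(uvals[-1])
    return ClassBreaks(edges=np.asarray(edges), method=JENKS)


def classify(grid: Grid, breaks: ClassBreaks) -> Grid:
    """Map each cell to a class index 1..k.

    Intervals are half-open lower-inclusive [e_i, e_{i+1}); the global
    maximum edge is closed into the top class. Values outside the edge
    range are clamped (count reported to the module logger).
    """
    vals = np.asarray(grid.values, dtype=float)
    edges = breaks.edges
    out = np.searchsorted(edges, vals, side="right")
    n_out = int(np.sum(((vals < edges[0]) | (vals > edges[-1])) & ~grid.nodata_mask))
    if n_out:
        logger.warning("classify: %d cells outside break range were clamped", n_out)
    out = np.clip(out, 1, breaks.k)
    out[grid.nodata_mask] = 0
    return grid.like(out.astype(np.int32))
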