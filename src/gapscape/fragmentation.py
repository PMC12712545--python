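"""Patch delineation, landscape metrics, and the composite
fragmentation index.

Four class-level metrics are computed per spatial window, with
Fragstats semantics:

* NP — number of patches (connected components; queen connectivity by
  default);
* PD — patch density, NP per km² of window;
* AREA_MN — mean patch area in km²;
* AI — aggregation index: 100 · g / g_max, where g counts rook
  (4-neighbour) like-adjacencies among class cells and g_max is the
  largest possible count for that cell total A (largest-integer-square
  rule: with n = floor(sqrt(A)) and m = A - n², g_max = 2n(n-1) when
  m = 0, 2n(n-1) + 2m - 1 when m <= n, 2n(n-1) + 2m - 2 when m > n).

The Composite Landscape Fragmentation Index (CLFI) is the equal-weight
mean of min-max normalized NP and PD and the inverted normalizations of
AREA_MN and AI (both fall as fragmentation rises):

    CLFI = (NP_norm + PD_norm + AREA_MN_adj + AI_adj) / 4  in [0, 1].

Normalization pools all windows of all periods jointly so per-period
mean CLFI values are directly comparable.  Windowed patch metrics of
the woodland+grassland mask are also exported at cell resolution as
habitat-patch (EHP) covariates for the distribution models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Grid, LandUseMap

QUEEN = np.ones((3, 3), dtype=int)
ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class PatchMetrics:
    np_: int          # number of patches
    pd: float         # patches per km^2
    area_mn: float    # km^2 (0 when no patches)
    ai: float         # [0, 100] (0 when undefined)


@dataclass
class CLFIResult:
    period: str
    window_metrics: list[PatchMetrics]
    components: np.ndarray   # (n_windows, 4): NP, PD, AREA_MN_adj, AI_adj
    clfi: np.ndarray         # per window
    mean_clfi: float         # over windows containing any class cell
    grid: Grid               # CLFI rasterized back to cells


def label_patches(mask: Grid, connectivity: str = "queen"
                  ) -> tuple[Grid, int]:
    """Connected components of True cells; labels follow scan order."""
    struct = QUEEN if connectivity == "queen" else ROOK
    m = np.asarray(mask.values, dtype=bool) & ~mask.nodata_mask
    labels, n = ndimage.label(m, structure=struct)
    return mask.like(labels.astype(np.int32)), int(n)


def _rook_adjacencies(m: np.ndarray) -> int:
    """Count of 4-neighbour like-adjacent cell pairs among True cells."""
    return int(np.sum(m[:, :-1] & m[:, 1:]) + np.sum(m[:-1, :] & m[1:, :]))


def max_adjacencies(A: int) -> int:
    """Largest possible rook adjacency count for A cells."""
    if A <= 1:
        return 0
    n = int(np.floor(np.sqrt(A)))
    m = A - n * n
    base = 2 * n * (n - 1)
    if m == 0:
        return base
    if m <= n:
        return base + 2 * m - 1
    return base + 2 * m - 2


def patch_metrics(mask: Grid, window_area_km2: float | None = None,
                  connectivity: str = "queen") -> PatchMetrics:
    """The four class-level metrics for one (windowed) binary mask."""
    m = np.asarray(mask.values, dtype=bool) & ~mask.nodata_mask
    if window_area_km2 is None:
        window_area_km2 = m.size * mask.cell_area_km2
    _, n_patches = label_patches(mask, connectivity)
    if n_patches == 0:
        return PatchMetrics(0, 0.0, 0.0, 0.0)
    area = float(m.sum()) * mask.cell_area_km2
    g = _rook_adjacencies(m)
    gmax = max_adjacencies(int(m.sum()))
    ai = 100.0 * g / gmax if gmax > 0 else 0.0
    return PatchMetrics(np_=n_patches, pd=n_patches / window_area_km2,
                        area_mn=area / n_patches, ai=ai)


def _windows(shape: tuple[int, int], size: int):
    rows, cols = shape
    for r0 in range(0, rows - size + 1, size):
        for c0 in range(0, cols - size + 1, size):
            yield r0, c0


def _window_grids(mask: Grid, size: int) -> list[tuple[int, int, Grid]]:
    out = []
    for r0, c0 in _windows(mask.shape, size):
        sub = Grid(values=mask.values[r0:r0 + size, c0:c0 + size],
                   nodata_mask=mask.nodata_mask[r0:r0 + size, c0:c0 + size],
                   cell_size_m=mask.cell_size_m)
        out.append((r0, c0, sub))
    return out


def _minmax(x: np.ndarray, invert: bool = False) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn("constant metric across all windows; component set "
                      "to neutral 0.5")
        return np.full(x.shape, 0.5)
    z = (x - lo) / (hi - lo)
    return 1.0 - z if invert else z


def clfi(masks: dict[str, Grid], window_size_cells: int = 20
         ) -> dict[str, CLFIResult]:
    """Windowed CLFI per period, normalized over all periods jointly.

    Each mask is tiled into non-overlapping windows (trailing partial
    windows are dropped); NP/PD/AREA_MN/AI are computed per window;
    NP and PD are min-max normalized and AREA_MN, AI inverted-normalized
    over the pooled windows of every period; the CLFI of a window is the
    equal-weight mean of the four components.  The per-period mean is
    taken over windows containing at least one class cell.
    """
    if window_size_cells < 10:
        raise ValueError("window size must be at least 10 cells per side")
    per_period: dict[str, list] = {}
    rows_all = []
    for period, mask in masks.items():
        wins = _window_grids(mask, window_size_cells)
        if len(wins) < 2:
            raise ValueError("need at least 2 windows; enlarge the grid or "
                             "shrink the window")
        area = (window_size_cells ** 2) * mask.cell_area_km2
        mets = [patch_metrics(w, area) for _, _, w in wins]
        per_period[period] = (wins, mets)
        rows_all.extend(mets)

    np_all = np.array([m.np_ for m in rows_all], dtype=float)
    pd_all = np.array([m.pd for m in rows_all])
    am_all = np.array([m.area_mn for m in rows_all])
    ai_all = np.array([m.ai / 100.0 for m in rows_all])
    comp_all = np.column_stack([
        _minmax(np_all), _minmax(pd_all),
        _minmax(am_all, invert=True), _minmax(ai_all, invert=True)])
    clfi_all = comp_all.mean(axis=1)

    out: dict[str, CLFIResult] = {}
    i = 0
    for period, (wins, mets) in per_period.items():
        k = len(wins)
        comps = comp_all[i:i + k]
        vals = clfi_all[i:i + k]
        i += k
        occupied = np.array([m.np_ > 0 for m in mets])
        mean_clfi = float(vals[occupied].mean()) if occupied.any() else 0.0
        grid_vals = np.full(masks[period].shape, np.nan)
        for (r0, c0, _), v in zip(wins, vals):
            grid_vals[r0:r0 + window_size_cells, c0:c0 + window_size_cells] = v
        g = masks[period].like(grid_vals, mask=np.isnan(grid_vals))
        out[period] = CLFIResult(period=period, window_metrics=mets,
                                 components=comps, clfi=vals,
                                 mean_clfi=mean_clfi, grid=g)
    return out


def ehp_covariates(lu: LandUseMap, window_size_cells: int = 20,
                   habitat_classes: tuple[str, ...] = ("woodland", "grassland")
                   ) -> list[Grid]:
    """Windowed patch metrics of the habitat mask as SDM covariates.

    Every cell carries its window's NP, PD, AREA_MN and AI; one grid per
    metric, aligned with the land-use grid (cells in trailing partial
    windows carry the metrics of the nearest full window row/column).
    """
    mask = lu.mask_of(*habitat_classes)
    rows, cols = mask.shape
    size = window_size_cells
    area = size * size * mask.cell_area_km2
    outs = [np.zeros((rows, cols)) for _ in range(4)]
    for r0 in range(0, rows, size):
        for c0 in range(0, cols, size):
            rr = min(r0, rows - size)
            cc = min(c0, cols - size)
            sub = Grid(values=mask.values[rr:rr + size, cc:cc + size],
                       nodata_mask=mask.nodata_mask[rr:rr + size, cc:cc + size],
                       cell_size_m=mask.cell_size_m)
            m = patch_metrics(sub, area)
            for arr, v in zip(outs, (m.np_, m.pd, m.area_mn, m.ai)):
                arr[r0:r0 + size, c0:c0 + size] = v
    return [lu.grid.like(a) for a in outs]
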