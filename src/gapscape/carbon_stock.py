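"""Carbon-stock bookkeeping over land-use classes.

Each land-use class carries a fixed carbon density c_i, the sum of four
pools (aboveground biomass, belowground biomass, soil organic carbon,
dead organic matter), in t/ha.  The landscape total is

    C = sum_i c_i * R_i

with R_i the area of class i in hectares.  For spatial reporting the
per-cell density map is zoned into six categories by natural breaks:
five Jenks classes over the distinct positive densities (low ...
high) plus a dedicated zero class ("none").
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Grid, LandUseMap, jenks_breaks

CARBON_ZONES = ["none", "low", "relatively_low", "moderate",
                "relatively_high", "high"]

# Literature-typical per-class pool densities (t/ha) for a six-class
# provincial landscape; overridable via CSV.
DEFAULT_DENSITY_ROWS = {
    # class: (above, below, soil, dead)
    1: (5.7, 1.1, 108.2, 1.0),    # cropland
    2: (35.4, 8.5, 150.3, 3.2),   # woodland
    3: (3.3, 8.9, 99.6, 1.5),     # grassland
    4: (0.4, 0.0, 0.0, 0.0),      # water
    5: (0.8, 0.0, 58.1, 0.0),     # construction
    6: (0.5, 0.0, 31.9, 0.0),     # unused
}


@dataclass
class CarbonDensityTable:
    """Per-class pool densities in t/ha; c_i is the four-pool sum."""

    pools: dict[int, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for code, p in self.pools.items():
            if len(p) != 4 or any(v < 0 for v in p):
                raise ValueError(f"class {code}: four non-negative pools required")

    def density(self, code: int) -> float:
        return float(sum(self.pools[code]))

    @property
    def densities(self) -> dict[int, float]:
        return {c: self.density(c) for c in self.pools}

    @classmethod
    def default(cls) -> "CarbonDensityTable":
        return cls(pools=dict(DEFAULT_DENSITY_ROWS))

    @classmethod
    def from_csv(cls, path: str) -> "CarbonDensityTable":
        """Columns: class, c_above, c_below, c_soil, c_dead."""
        df = pd.read_csv(path)
        pools = {int(r["class"]): (float(r["c_above"]), float(r["c_below"]),
                                   float(r["c_soil"]), float(r["c_dead"]))
                 for _, r in df.iterrows()}
        return cls(pools=pools)

    def to_csv(self, path: str) -> None:
        rows = [{"class": c, "c_above": p[0], "c_below": p[1],
                 "c_soil": p[2], "c_dead": p[3]}
                for c, p in sorted(self.pools.items())]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class CarbonResult:
    density_grid: Grid        # t/ha
    total_C: float            # tonnes
    zones: Grid               # 0 = none, 1 = low ... 5 = high
    zone_fractions: dict[str, float]

    def summary(self) -> dict:
        return {"total_C_t": self.total_C, "zone_fractions": self.zone_fractions}


def carbon_map(lu: LandUseMap, table: CarbonDensityTable | None = None
               ) -> CarbonResult:
    """Per-cell carbon density, landscape total, and six-level zoning.

    Total carbon is computed class-wise (density x class area in ha,
    summed over classes), which equals the per-cell sum exactly up to
    summation order.  Zoning: Jenks k=5 over the distinct positive
    densities present (fewer classes merge gracefully when fewer than
    five distinct positive densities occur) plus zone 0 for zero
    density.
    """
    table = table or CarbonDensityTable.default()
    codes = np.unique(lu.grid.valid().astype(int))
    missing = [int(c) for c in codes if c not in table.pools]
    if missing:
        raise KeyError(f"carbon table missing land-use classes: {missing}")

    valid = ~lu.grid.nodata_mask
    dens = np.zeros(lu.grid.shape)
    area_ha = lu.grid.cell_area_ha
    total = 0.0
    for code in codes:
        sel = (lu.grid.values == code) & valid
        c_i = table.density(int(code))
        dens[sel] = c_i
        total += c_i * (float(sel.sum()) * area_ha)   # C_i * R_i

    pos = np.unique(dens[valid & (dens > 0)])
    k = min(5, len(pos))
    zones = np.zeros(lu.grid.shape, dtype=np.int32)
    if k >= 1:
        if k == 1:
            edges = np.array([pos[0], pos[0] + 1.0])
        else:
            edges = jenks_breaks(pos, k).edges
        # assign positive densities to zones 1..k, top classes first when
        # fewer than 5 distinct densities (classes merge top-down)
        zi = np.searchsorted(edges, dens, side="right")
        zi = np.clip(zi, 1, k) + (5 - k)
        zones[valid & (dens > 0)] = zi[valid & (dens > 0)]
    nval = int(valid.sum())
    fractions = {name: float(np.sum((zones == i) & valid)) / nval
                 for i, name in enumerate(CARBON_ZONES)}
    return CarbonResult(density_grid=lu.grid.like(dens), total_C=total,
                        zones=lu.grid.like(zones), zone_fractions=fractions)


def carbon_change(r_t0: CarbonResult, r_t1: CarbonResult) -> dict:
    """Total and per-cell carbon-stock change between two periods."""
    r_t0.density_grid.require_aligned(r_t1.density_grid, "carbon grids")
    area_ha = r_t0.density_grid.cell_area_ha
    delta = (r_t1.density_grid.values - r_t0.density_grid.values) * area_ha
    return {
        "delta_total_t": r_t1.total_C - r_t0.total_C,
        "delta_grid": r_t0.density_grid.like(delta),  # tonnes per cell
    }


def write_summary(result: CarbonResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(result.summary(), fh, indent=2)
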