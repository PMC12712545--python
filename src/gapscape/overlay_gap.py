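"""Species–habitat–carbon overlay and persistent-gap intersection.

Three binary layers — the union of per-species high-suitability masks
(S), the high-value habitat mask (H), and the high-carbon zones (C) —
partition the landscape into the eight truth-table categories, from
three-way hotspots down to non-significant areas.

Conservation gaps identified per period (planning units with selection
frequency above the cutoff, outside existing reserves) are intersected
across periods: units flagged as gaps in every period form the
persistent gap set proposed for future protection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Grid

#: category code -> name, in truth-table order over (S, H, C)
OVERLAY_CATEGORIES = {
    7: "hotspot",           # S & H & C
    6: "species_habitat",   # S & H
    5: "species_carbon",    # S & C
    4: "habitat_carbon",    # H & C
    3: "species_only",
    2: "habitat_only",
    1: "carbon_only",
    0: "non_significant",
}


@dataclass
class OverlayMap:
    categories: Grid
    shares: dict[str, float]


@dataclass
class GapSet:
    per_period: dict[str, set[int]]
    persistent: set[int] = field(default_factory=set)

    @property
    def per_period_counts(self) -> dict[str, int]:
        return {p: len(s) for p, s in self.per_period.items()}


def overlay(species_high: Grid, habitat_high: Grid,
            carbon_high: Grid) -> OverlayMap:
    """Classify each cell by which of the S/H/C masks cover it."""
    species_high.require_aligned(habitat_high, "overlay masks")
    species_high.require_aligned(carbon_high, "overlay masks")
    S = np.asarray(species_high.values, dtype=bool)
    H = np.asarray(habitat_high.values, dtype=bool)
    C = np.asarray(carbon_high.values, dtype=bool)
    valid = ~(species_high.nodata_mask | habitat_high.nodata_mask
              | carbon_high.nodata_mask)
    cat = np.zeros(S.shape, dtype=np.int32)
    cat[S & H & C] = 7
    cat[S & H & ~C] = 6
    cat[S & ~H & C] = 5
    cat[~S & H & C] = 4
    cat[S & ~H & ~C] = 3
    cat[~S & H & ~C] = 2
    cat[~S & ~H & C] = 1
    n = int(valid.sum())
    shares = {name: float(np.sum((cat == code) & valid)) / n
              for code, name in OVERLAY_CATEGORIES.items()}
    return OverlayMap(categories=species_high.like(cat, mask=~valid),
                      shares=shares)


def persistent_gaps(per_period: dict[str, set[int]]) -> GapSet:
    """Units flagged as gaps in every period."""
    if len(per_period) < 2:
        raise ValueError("need gap sets for at least 2 periods")
    sets = [set(s) for s in per_period.values()]
    persistent = set.intersection(*sets)
    return GapSet(per_period={p: set(s) for p, s in per_period.items()},
                  persistent=persistent)


def species_union_mask(high_masks: list[Grid], min_richness: int = 1) -> Grid:
    """Union (richness >= min_richness) of per-species high masks."""
    if not high_masks:
        raise ValueError("no species masks")
    count = np.zeros(high_masks[0].shape, dtype=int)
    for m in high_masks:
        high_masks[0].require_aligned(m, "species masks")
        count += np.asarray(m.values, dtype=bool)
    return high_masks[0].like(count >= min_richness)


def carbon_high_mask(zones: Grid, top_k: int = 2) -> Grid:
    """Top carbon zones (default: high + relatively high, zones 4-5)."""
    return zones.like((zones.values >= 6 - top_k) & ~zones.nodata_mask)
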