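"""Human-Disturbance-Index cost surface via the entropy weight method.

The planning cost combines disturbance indicators (by default a GDP
surface and a land-use disturbance score) as

    HDI = sum_j W_j * standardized(HDI_j)

with objective weights from the entropy weight method: each indicator
is min-max standardized over the n valid cells (inverted for
cost-direction indicators), turned into a distribution
p_ij = x_ij / sum_i x_ij, its Shannon entropy
e_j = -(1/ln n) sum_i p_ij ln p_ij computed (0·ln 0 := 0), and

    W_j = (1 - e_j) / sum_k (1 - e_k).

Indicators with no spatial variation carry zero information (e_j = 1)
and receive zero weight.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import Grid, LandUseMap

# Default disturbance score per land-use class.
DEFAULT_DISTURBANCE = {
    "construction": 1.0, "cropland": 0.6, "unused": 0.3,
    "grassland": 0.2, "woodland": 0.1, "water": 0.1,
}


@dataclass
class IndicatorSet:
    names: list[str]
    grids: list[Grid]
    directions: list[str] = field(default_factory=list)  # benefit | cost

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("need at least one indicator")
        if len(self.names) != len(self.grids):
            raise ValueError("names and grids length mismatch")
        if not self.directions:
            self.directions = ["benefit"] * len(self.grids)
        for g in self.grids[1:]:
            self.grids[0].require_aligned(g, "indicator grids")


@dataclass
class EntropyWeights:
    weights: np.ndarray
    entropies: np.ndarray
    names: list[str]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({n: float(w) for n, w in zip(self.names, self.weights)},
                      fh, indent=2)


def landuse_disturbance(lu: LandUseMap,
                        score_table: dict[str, float] | None = None) -> Grid:
    """Per-cell disturbance score looked up from the land-use class."""
    table = score_table or DEFAULT_DISTURBANCE
    out = np.zeros(lu.grid.shape)
    for code, name in lu.legend.items():
        if name not in table:
            raise KeyError(f"no disturbance score for land-use class {name!r}")
        out[lu.grid.values == code] = table[name]
    return lu.grid.like(out)


def _standardize(ind: IndicatorSet) -> np.ndarray:
    """Min-max standardized indicator columns over valid cells (n x J)."""
    valid = ~ind.grids[0].nodata_mask
    cols = []
    for g, direction in zip(ind.grids, ind.directions):
        x = g.values[valid].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            z = np.zeros_like(x)
        else:
            z = (x - lo) / (hi - lo)
            if direction == "cost":
                z = 1.0 - z
        cols.append(z)
    return np.column_stack(cols)


def entropy_weights(ind: IndicatorSet) -> EntropyWeights:
    """Objective indicator weights from Shannon entropy of each column."""
    Z = _standardize(ind)
    n, J = Z.shape
    ent = np.ones(J)
    for j in range(J):
        col = Z[:, j]
        tot = col.sum()
        if tot <= 0:
            warnings.warn(f"indicator {ind.names[j]!r} is constant; weight 0")
            continue
        p = col / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        ent[j] = -plogp.sum() / np.log(n)
    info = 1.0 - ent
    if info.sum() <= 0:
        raise ValueError("all indicators are constant; cannot weight")
    return EntropyWeights(weights=info / info.sum(), entropies=ent,
                          names=list(ind.names))


def hdi(ind: IndicatorSet, w: EntropyWeights | None = None) -> Grid:
    """Entropy-weighted disturbance surface in [0, 1]."""
    if w is None:
        w = entropy_weights(ind)
    if len(w.weights) != len(ind.grids):
        raise ValueError("weight/indicator count mismatch")
    Z = _standardize(ind)
    valid = ~ind.grids[0].nodata_mask
    combined = Z @ w.weights
    out = np.zeros(ind.grids[0].shape)
    out[valid] = combined
    return ind.grids[0].like(out)
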