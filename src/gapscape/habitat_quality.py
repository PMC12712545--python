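"""Habitat-quality assessment (InVEST-style half-saturation model).

Per-cell habitat quality combines a land-use habitat score H_j with a
threat-driven degradation level D_xj:

    Q_xj = H_j * (1 - D^z / (D^z + k^z))

with scaling constant z (default 2.5) and half-saturation constant k
(by default half the maximum observed degradation, so the most degraded
cell loses half its habitat score at D = k).  Degradation sums
weight-normalized, distance-decayed threat impacts scaled by the
land-use class's sensitivity to each threat and by cell accessibility:

    D_x = sum_r (w_r / sum w) * impact_r(x) * beta_x * S_{j(x), r}

Threat impact at a cell is the decay-weighted mean over source cells
within the threat's maximum distance: decay is linear (1 - d/d_max) or
exponential (exp(-2.99 d / d_max), ~0.05 at d_max), and the sum over
sources is divided by the number of contributing source cells so the
impact stays in [0, 1].

Quality is valued on five equal-interval levels over [0, 1]; the top
two levels (moderately high and high) form the high-value habitat mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .core_io import (Grid, LandUseMap, classify, equal_interval_breaks,
                      read_grid)

HQ_LEVELS = ["low", "moderately_low", "medium", "moderately_high", "high"]


@dataclass
class ThreatSpec:
    name: str
    weight: float
    max_dist_km: float
    decay: str  # "linear" | "exponential"
    source: Grid

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"threat {self.name}: weight must be >= 0")
        if self.max_dist_km <= 0:
            raise ValueError(f"threat {self.name}: max_dist_km must be > 0")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"threat {self.name}: unknown decay {self.decay!r}")


@dataclass
class SensitivityTable:
    """Habitat scores and threat sensitivities per land-use class."""

    habitat_score: dict[int, float]
    sensitivity: dict[tuple[int, str], float]
    accessibility: Grid | None = None  # beta in [0,1]; default all ones

    def __post_init__(self) -> None:
        for c, h in self.habitat_score.items():
            if not 0 <= h <= 1:
                raise ValueError(f"habitat score for class {c} outside [0,1]")
        for key, s in self.sensitivity.items():
            if not 0 <= s <= 1:
                raise ValueError(f"sensitivity {key} outside [0,1]")

    def h_grid(self, lu: LandUseMap) -> np.ndarray:
        out = np.zeros(lu.grid.shape)
        for code, h in self.habitat_score.items():
            out[lu.grid.values == code] = h
        return out

    def s_grid(self, lu: LandUseMap, threat: str) -> np.ndarray:
        out = np.zeros(lu.grid.shape)
        for code in self.habitat_score:
            s = self.sensitivity.get((code, threat), 0.0)
            out[lu.grid.values == code] = s
        return out

    @classmethod
    def from_csv(cls, path: str, accessibility: Grid | None = None
                 ) -> "SensitivityTable":
        """Rows = land-use codes; columns HABITAT plus S_<threat-name>."""
        df = pd.read_csv(path, index_col=0)
        hab = {int(c): float(df.loc[c, "HABITAT"]) for c in df.index}
        sens = {}
        for col in df.columns:
            if col.startswith("S_"):
                t = col[2:]
                for c in df.index:
                    sens[(int(c), t)] = float(df.loc[c, col])
        return cls(habitat_score=hab, sensitivity=sens,
                   accessibility=accessibility)


# Packaged default parameterization for a six-class provincial landscape.
# Threat tables of the original studies are rarely published in full;
# these are literature-typical values and fully overridable via YAML/CSV.
DEFAULT_HABITAT_SCORE = {1: 0.4, 2: 1.0, 3: 0.8, 4: 0.7, 5: 0.0, 6: 0.1}
DEFAULT_SENSITIVITY = {
    # (class, threat): sensitivity
    **{(c, "cropland"): s for c, s in
       {1: 0.0, 2: 0.6, 3: 0.5, 4: 0.6, 5: 0.0, 6: 0.2}.items()},
    **{(c, "construction"): s for c, s in
       {1: 0.5, 2: 0.9, 3: 0.8, 4: 0.8, 5: 0.0, 6: 0.3}.items()},
    **{(c, "road"): s for c, s in
       {1: 0.4, 2: 0.7, 3: 0.6, 4: 0.6, 5: 0.0, 6: 0.2}.items()},
}
DEFAULT_THREAT_PARAMS = {
    "cropland": {"weight": 0.6, "max_dist_km": 1.0, "decay": "linear"},
    "construction": {"weight": 1.0, "max_dist_km": 8.0, "decay": "exponential"},
    "road": {"weight": 0.7, "max_dist_km": 2.0, "decay": "linear"},
}

EXP_DECAY_CONST = 2.99  # impact ~0.05 at max distance


@dataclass
class HabitatQualityResult:
    degradation: Grid
    quality: Grid
    k: float
    z: float
    classes: Grid
    high_value_mask: Grid
    mean_hqi: float
    class_fractions: dict[str, float]

    def summary(self) -> dict:
        return {"mean_hqi": self.mean_hqi, "k": self.k, "z": self.z,
                "class_fractions": self.class_fractions}


def _decay_kernel(max_dist_km: float, decay: str, cell_km: float) -> np.ndarray:
    """Decay weights on a (2R+1)² cell-offset stencil; 0 beyond max_dist."""
    R = int(np.floor(max_dist_km / cell_km))
    off = np.arange(-R, R + 1)
    dy, dx = np.meshgrid(off, off, indexing="ij")
    d = np.hypot(dy, dx) * cell_km
    if decay == "linear":
        w = 1.0 - d / max_dist_km
    else:
        w = np.exp(-EXP_DECAY_CONST * d / max_dist_km)
    w[d > max_dist_km] = 0.0
    return w


def threat_impact(threat: ThreatSpec, geom: Grid) -> Grid:
    """Distance-decayed mean threat intensity per cell, in [0, 1].

    impact(x) = sum_{y within d_max, r_y > 0} r_y decay(d_xy) / n_contrib.
    """
    threat.source.require_aligned(geom, "threat source and study grid")
    cell_km = geom.cell_size_m / 1000.0
    r = np.where(threat.source.nodata_mask, 0.0, threat.source.values)
    if np.all(r <= 0):
        warnings.warn(f"threat {threat.name}: empty source raster, impact 0")
        return geom.like(np.zeros(geom.shape))
    kern = _decay_kernel(threat.max_dist_km, threat.decay, cell_km)
    num = ndimage.convolve(r, kern, mode="constant", cval=0.0)
    contrib = ndimage.convolve((r > 0).astype(float),
                               (kern > 0).astype(float),
                               mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        impact = np.where(contrib > 0, num / contrib, 0.0)
    return geom.like(np.clip(impact, 0.0, 1.0))


def degradation(threats: list[ThreatSpec], sens: SensitivityTable,
                lu: LandUseMap) -> Grid:
    """Weight-normalized, sensitivity-scaled total degradation D_x >= 0."""
    total_w = sum(t.weight for t in threats)
    if total_w <= 0:
        raise ValueError("threat weights sum to zero")
    beta = (np.ones(lu.grid.shape) if sens.accessibility is None
            else sens.accessibility.values)
    D = np.zeros(lu.grid.shape)
    for t in threats:
        imp = threat_impact(t, lu.grid).values
        D += (t.weight / total_w) * imp * beta * sens.s_grid(lu, t.name)
    return lu.grid.like(D)


def quality(D: Grid, lu: LandUseMap, sens: SensitivityTable,
            z: float = 2.5, k: float | str = "auto") -> HabitatQualityResult:
    """Half-saturation habitat quality with five-level valuation.

    ``k="auto"`` sets the half-saturation constant to half the maximum
    degradation; if no cell is degraded, k falls back to 0.5 (the
    transform then leaves Q = H everywhere).
    """
    if np.any(D.valid() < 0):
        raise ValueError("degradation must be non-negative")
    if k == "auto":
        dmax = float(D.valid().max()) if D.valid().size else 0.0
        if dmax == 0.0:
            warnings.warn("no degradation anywhere; k set to 0.5, Q = H")
            k_val = 0.5
        else:
            k_val = dmax / 2.0
    else:
        k_val = float(k)
    H = sens.h_grid(lu)
    Dz = np.power(D.values, z, where=D.values > 0,
                  out=np.zeros_like(D.values, dtype=float))
    Q = H * (1.0 - Dz / (Dz + k_val ** z))
    Qg = lu.grid.like(Q)
    breaks = equal_interval_breaks(None, 5, bounds=(0.0, 1.0))
    classes = classify(Qg, breaks)
    high = (classes.values >= 4) & ~Qg.nodata_mask
    valid = ~Qg.nodata_mask
    nval = int(valid.sum())
    fractions = {lvl: float(np.sum((classes.values == i + 1) & valid)) / nval
                 for i, lvl in enumerate(HQ_LEVELS)}
    return HabitatQualityResult(
        degradation=D, quality=Qg, k=k_val, z=z, classes=classes,
        high_value_mask=Qg.like(high), mean_hqi=float(Q[valid].mean()),
        class_fractions=fractions)


def hq_change(q_t0: Grid, q_t1: Grid, tol: float = 0.01) -> dict:
    """Per-cell change classification between two quality maps.

    Returns the change grid (1 improved, 0 stable, -1 degraded) and the
    area fraction of each category.
    """
    q_t0.require_aligned(q_t1, "quality grids")
    delta = q_t1.values - q_t0.values
    change = np.zeros(delta.shape, dtype=np.int32)
    change[delta > tol] = 1
    change[delta < -tol] = -1
    valid = ~(q_t0.nodata_mask | q_t1.nodata_mask)
    change_grid = q_t0.like(change, mask=~valid)
    n = int(valid.sum())
    return {
        "change": change_grid,
        "fraction_improved": float(np.sum((change == 1) & valid)) / n,
        "fraction_stable": float(np.sum((change == 0) & valid)) / n,
        "fraction_degraded": float(np.sum((change == -1) & valid)) / n,
    }


def default_threats(threat_sources: dict[str, Grid],
                    params: dict | None = None) -> list[ThreatSpec]:
    """Build ThreatSpecs from source grids using packaged default params."""
    params = params or DEFAULT_THREAT_PARAMS
    out = []
    for name, src in threat_sources.items():
        p = params.get(name)
        if p is None:
            raise KeyError(f"no threat parameters for {name!r}")
        out.append(ThreatSpec(name=name, weight=p["weight"],
                              max_dist_km=p["max_dist_km"],
                              decay=p["decay"], source=src))
    return out


def default_sensitivity(accessibility: Grid | None = None) -> SensitivityTable:
    return SensitivityTable(habitat_score=dict(DEFAULT_HABITAT_SCORE),
                            sensitivity=dict(DEFAULT_SENSITIVITY),
                            accessibility=accessibility)


def threats_from_yaml(path: str) -> list[ThreatSpec]:
    """Load per-threat name/weight/max_dist/decay/source-path from YAML."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    out = []
    for entry in spec["threats"]:
        out.append(ThreatSpec(
            name=entry["name"], weight=float(entry["weight"]),
            max_dist_km=float(entry["max_dist_km"]), decay=entry["decay"],
            source=read_grid(entry["source"])))
    return out


def write_summary(result: HabitatQualityResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(result.summary(), fh, indent=2)
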