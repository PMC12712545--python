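"""Systematic conservation planning by simulated annealing.

Planning units (grid blocks by default, polygons optionally) carry a
cost (mean Human Disturbance Index), per-feature amounts (km² of each
conservation feature inside the unit), shared boundary lengths with
their neighbours, and a reserved flag for units already inside nature
reserves.  A reserve portfolio is scored by the Marxan-style objective

    value = sum_{selected} cost
          + BLM * exposed boundary of the selected set
          + sum_f SPF_f * penalty_f

where the exposed boundary counts shared edges with exactly one side
selected plus outer edges of selected units, and penalty_f scales a
per-feature base penalty (a greedy cost-to-meet-target estimate) by the
fractional shortfall max(0, (T_f - held_f) / T_f).

Portfolios are optimized by simulated annealing over single-unit flips
(geometric cooling, initial temperature auto-calibrated from random
probes, final greedy descent).  Repeated runs yield the per-unit
selection frequency (ssoln); available units selected in more than 65%
of runs are conservation gaps.  A BLM sensitivity sweep reports the
cost-versus-boundary trade-off and its knee point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Grid


# ---------------------------------------------------------------------------
# planning units
# ---------------------------------------------------------------------------

@dataclass
class PlanningUnitSet:
    ids: np.ndarray                 # (n,)
    costs: np.ndarray               # (n,)
    reserved: np.ndarray            # (n,) bool
    amounts: np.ndarray             # (n, F) km^2 of each feature
    feature_names: list[str]
    neighbors: list[np.ndarray]     # per unit: indices of adjacent units
    shared_lengths: list[np.ndarray]  # per unit: shared boundary km
    outer: np.ndarray               # (n,) outer (unshared) edge km
    geometries: list | None = None  # polygon coordinate rings (GeoJSON style)
    unit_grid: Grid | None = None   # cell -> unit index (-1 outside)

    def __post_init__(self) -> None:
        if np.any(self.costs < 0):
            raise ValueError("unit costs must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.amounts.shape[1]

    def boundary_matrix(self) -> dict[tuple[int, int], float]:
        out = {}
        for i in range(self.n):
            for j, L in zip(self.neighbors[i], self.shared_lengths[i]):
                if i < j:
                    out[(i, int(j))] = float(L)
        return out


@dataclass
class FeatureTargets:
    feature_names: list[str]
    targets: np.ndarray   # km^2
    spf: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.spf = np.asarray(self.spf, dtype=float)
        if np.any(self.spf <= 0):
            raise ValueError("SPF must be positive")

    @classmethod
    def proportional(cls, pu: PlanningUnitSet, fraction: float = 0.3,
                     spf: float | np.ndarray = 3.0) -> "FeatureTargets":
        """Targets as a fraction (default 30%) of each feature's extent."""
        totals = pu.amounts.sum(axis=0)
        spf_arr = np.full(pu.n_features, spf) if np.isscalar(spf) else np.asarray(spf)
        return cls(feature_names=list(pu.feature_names),
                   targets=fraction * totals, spf=spf_arr)


@dataclass
class SAParams:
    blm: float = 0.001
    n_runs: int = 100
    iterations: int | None = None     # default: max(2000, 50 * n_units)
    initial_temperature: float | None = None  # default: auto-calibrated
    cooling: float | None = None      # default: reach T0/1000 at the end
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blm < 0:
            raise ValueError("blm must be >= 0")
        if self.cooling is not None and not 0 < self.cooling < 1:
            raise ValueError("cooling must be in (0, 1)")
        if self.iterations is not None and self.iterations <= 0:
            raise ValueError("iterations must be positive")


@dataclass
class Solution:
    selected: np.ndarray   # bool (n,), reserved forced True
    value: float
    cost_term: float
    boundary_term: float   # BLM * boundary length
    penalty_term: float


@dataclass
class SelectionFrequency:
    ssoln: np.ndarray      # per-unit fraction of runs selected
    best: Solution
    n_runs: int


def build_units(hdi: Grid, feature_masks: dict[str, Grid],
                reserves: Grid, block_size: int = 10,
                reserve_overlap: float = 0.5) -> PlanningUnitSet:
    """Grid-block planning units.

    Blocks of ``block_size``² cells become units (blocks with no valid
    cell are dropped).  Unit cost is the mean HDI over its valid cells;
    amounts count feature-mask cells times cell area; boundaries are
    shared valid-cell edges times cell size; edges facing nodata or the
    grid border are outer edges.  Units whose reserve coverage exceeds
    ``reserve_overlap`` are flagged reserved.
    """
    rows, cols = hdi.shape
    valid = ~hdi.nodata_mask
    cell_km = hdi.cell_size_m / 1000.0

    uid = np.full((rows, cols), -1, dtype=int)
    blocks = []
    next_id = 0
    for r0 in range(0, rows, block_size):
        for c0 in range(0, cols, block_size):
            sl = (slice(r0, min(r0 + block_size, rows)),
                  slice(c0, min(c0 + block_size, cols)))
            if not valid[sl].any():
                warnings.warn("dropping empty planning unit block")
                continue
            sub = uid[sl]
            sub[valid[sl]] = next_id
            blocks.append((r0, c0))
            next_id += 1
    n = next_id

    costs = np.zeros(n)
    resfrac = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(counts, uid[valid], 1.0)
    np.add.at(costs, uid[valid], hdi.values[valid])
    costs /= counts
    np.add.at(resfrac, uid[valid], np.asarray(reserves.values, bool)[valid])
    resfrac /= counts
    reserved = resfrac > reserve_overlap

    F = len(feature_masks)
    names = list(feature_masks)
    amounts = np.zeros((n, F))
    area = hdi.cell_area_km2
    for f, name in enumerate(names):
        m = np.asarray(feature_masks[name].values, bool) & valid
        np.add.at(amounts[:, f], uid[m], area)

    shared: dict[tuple[int, int], float] = {}
    outer = np.zeros(n)

    def _edges(a: np.ndarray, b: np.ndarray) -> None:
        both = (a >= 0) & (b >= 0)
        diff = both & (a != b)
        for i, j in zip(a[diff], b[diff]):
            key = (min(i, j), max(i, j))
            shared[key] = shared.get(key, 0.0) + cell_km
        only_a = (a >= 0) & (b < 0)
        np.add.at(outer, a[only_a], cell_km)
        only_b = (b >= 0) & (a < 0)
        np.add.at(outer, b[only_b], cell_km)

    _edges(uid[:, :-1].ravel(), uid[:, 1:].ravel())
    _edges(uid[:-1, :].ravel(), uid[1:, :].ravel())
    # grid-border edges
    for border in (uid[0, :], uid[-1, :], uid[:, 0], uid[:, -1]):
        np.add.at(outer, border[border >= 0], cell_km)

    neighbors: list[list[int]] = [[] for _ in range(n)]
    lengths: list[list[float]] = [[] for _ in range(n)]
    for (i, j), L in shared.items():
        neighbors[i].append(j)
        lengths[i].append(L)
        neighbors[j].append(i)
        lengths[j].append(L)

    geoms = []
    for r0, c0 in blocks:
        x0, y0 = hdi.origin
        c = hdi.cell_size_m
        r1, c1 = min(r0 + block_size, rows), min(c0 + block_size, cols)
        ring = [[x0 + c0 * c, y0 - r0 * c], [x0 + c1 * c, y0 - r0 * c],
                [x0 + c1 * c, y0 - r1 * c], [x0 + c0 * c, y0 - r1 * c],
                [x0 + c0 * c, y0 - r0 * c]]
        geoms.append([ring])

    return PlanningUnitSet(
        ids=np.arange(n), costs=costs, reserved=reserved, amounts=amounts,
        feature_names=names,
        neighbors=[np.array(nb, dtype=int) for nb in neighbors],
        shared_lengths=[np.array(ls) for ls in lengths],
        outer=outer, geometries=geoms, unit_grid=hdi.like(uid))


def build_units_from_polygons(geojson_path: str, hdi: Grid,
                              feature_masks: dict[str, Grid], reserves: Grid,
                              reserve_overlap: float = 0.5) -> PlanningUnitSet:
    """Polygon planning units from a GeoJSON FeatureCollection.

    Cells are assigned to the polygon containing their center; shared
    boundary lengths come from pairwise boundary intersections.
    """
    from shapely.geometry import shape

    with open(geojson_path) as fh:
        gj = json.load(fh)
    polys = [shape(feat["geometry"]) for feat in gj["features"]]
    rows, cols = hdi.shape
    valid = ~hdi.nodata_mask
    uid = np.full((rows, cols), -1, dtype=int)
    from shapely.strtree import STRtree
    tree = STRtree(polys)
    from shapely.geometry import Point
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            pt = Point(*hdi.cell_center(r, c))
            for idx in tree.query(pt):
                if polys[idx].contains(pt):
                    uid[r, c] = idx
                    break
    n = len(polys)
    counts = np.zeros(n)
    costs = np.zeros(n)
    resfrac = np.zeros(n)
    sel = uid >= 0
    np.add.at(counts, uid[sel], 1.0)
    np.add.at(costs, uid[sel], hdi.values[sel])
    np.add.at(resfrac, uid[sel], np.asarray(reserves.values, bool)[sel])
    keep = counts > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty polygon units")
    remap = -np.ones(n, dtype=int)
    remap[keep] = np.arange(keep.sum())
    polys = [p for p, k in zip(polys, keep) if k]
    counts, costs, resfrac = counts[keep], costs[keep], resfrac[keep]
    uid = np.where(sel, remap[np.clip(uid, 0, None)], -1)
    n = len(polys)
    costs = costs / counts
    reserved = resfrac / counts > reserve_overlap

    names = list(feature_masks)
    amounts = np.zeros((n, len(names)))
    for f, name in enumerate(names):
        m = np.asarray(feature_masks[name].values, bool) & (uid >= 0)
        np.add.at(amounts[:, f], uid[m], hdi.cell_area_km2)

    neighbors: list[list[int]] = [[] for _ in range(n)]
    lengths: list[list[float]] = [[] for _ in range(n)]
    shared_total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = polys[i].boundary.intersection(polys[j].boundary)
            L = inter.length / 1000.0
            if L > 0:
                neighbors[i].append(j)
                lengths[i].append(L)
                neighbors[j].append(i)
                lengths[j].append(L)
                shared_total[i] += L
                shared_total[j] += L
    outer = np.maximum(0.0, np.array([p.boundary.length / 1000.0
                                      for p in polys]) - shared_total)
    geoms = [[list(p.exterior.coords)] if p.geom_type == "Polygon" else None
             for p in polys]
    return PlanningUnitSet(
        ids=np.arange(n), costs=costs, reserved=reserved, amounts=amounts,
        feature_names=names,
        neighbors=[np.array(nb, dtype=int) for nb in neighbors],
        shared_lengths=[np.array(ls) for ls in lengths],
        outer=outer, geometries=geoms, unit_grid=hdi.like(uid))


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def base_penalties(pu: PlanningUnitSet, ft: FeatureTargets) -> np.ndarray:
    """Greedy cost-to-meet-target estimate per feature.

    Units with a positive amount of the feature are taken in order of
    cost per unit of feature until the target is met; the base penalty
    is the summed cost of those units.  This anchors the shortfall
    penalty on the scale of the cost it would take to fix it.
    """
    out = np.zeros(ft.targets.shape)
    for f, T in enumerate(ft.targets):
        if T <= 0:
            continue
        a = pu.amounts[:, f]
        has = a > 0
        if not has.any():
            warnings.warn(
                f"feature {ft.feature_names[f]!r}: no unit contains it")
            out[f] = ft.targets[f]  # arbitrary positive scale
            continue
        ratio = pu.costs[has] / a[has]
        order = np.argsort(ratio, kind="stable")
        idx = np.flatnonzero(has)[order]
        cum = np.cumsum(a[idx])
        need = int(np.searchsorted(cum, T))
        need = min(need, len(idx) - 1)
        out[f] = pu.costs[idx[:need + 1]].sum()
        if cum[-1] < T:
            warnings.warn(
                f"feature {ft.feature_names[f]!r}: target {T:.1f} exceeds "
                f"total extent {cum[-1]:.1f}; unattainable")
    return out


def _shortfall(held: np.ndarray, targets: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(targets > 0, (targets - held) / targets, 0.0)
    return np.maximum(0.0, s)


def exposed_boundary(sel: np.ndarray, pu: PlanningUnitSet) -> float:
    """Outer edges of selected units plus shared edges with one side selected."""
    total = float(pu.outer[sel].sum())
    for i in np.flatnonzero(sel):
        nb = pu.neighbors[i]
        if len(nb):
            total += float(pu.shared_lengths[i][~sel[nb]].sum())
    return total


def objective(selected: np.ndarray, pu: PlanningUnitSet, ft: FeatureTargets,
              blm: float, base: np.ndarray | None = None) -> Solution:
    """Evaluate the three-term objective for one portfolio."""
    sel = np.asarray(selected, dtype=bool).copy()
    sel[pu.reserved] = True
    if base is None:
        base = base_penalties(pu, ft)
    cost = float(pu.costs[sel].sum())
    boundary = exposed_boundary(sel, pu)
    held = pu.amounts[sel].sum(axis=0)
    penalty = float(np.sum(ft.spf * base * _shortfall(held, ft.targets)))
    return Solution(selected=sel, value=cost + blm * boundary + penalty,
                    cost_term=cost, boundary_term=blm * boundary,
                    penalty_term=penalty)


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------

class _Annealer:
    """Incremental-objective annealer over single-unit flips."""

    def __init__(self, pu: PlanningUnitSet, ft: FeatureTargets,
                 blm: float, base: np.ndarray):
        self.pu = pu
        self.ft = ft
        self.blm = blm
        self.base = base
        self.spf_base = ft.spf * base
        self.available = np.flatnonzero(~pu.reserved)

    def init_state(self, rng: np.random.Generator) -> None:
        sel = rng.random(self.pu.n) < 0.5
        sel[self.pu.reserved] = True
        self.sel = sel
        self.held = self.pu.amounts[sel].sum(axis=0)
        self.cost = float(self.pu.costs[sel].sum())
        self.boundary = exposed_boundary(sel, self.pu)
        self.penalty = float(np.sum(self.spf_base
                                    * _shortfall(self.held, self.ft.targets)))

    def value(self) -> float:
        return self.cost + self.blm * self.boundary + self.penalty

    def delta(self, u: int) -> tuple[float, float, float, float]:
        """Objective change if unit u were flipped."""
        pu = self.pu
        sign = -1.0 if self.sel[u] else 1.0
        dcost = sign * pu.costs[u]
        nb = pu.neighbors[u]
        if len(nb):
            db = pu.outer[u] + float(
                pu.shared_lengths[u][~self.sel[nb]].sum()
                - pu.shared_lengths[u][self.sel[nb]].sum())
        else:
            db = pu.outer[u]
        dbound = sign * db
        new_held = self.held + sign * pu.amounts[u]
        dpen = float(np.sum(self.spf_base
                            * (_shortfall(new_held, self.ft.targets)
                               - _shortfall(self.held, self.ft.targets))))
        return dcost + self.blm * dbound + dpen, dcost, dbound, dpen

    def flip(self, u: int, deltas) -> None:
        dval, dcost, dbound, dpen = deltas
        sign = -1.0 if self.sel[u] else 1.0
        self.sel[u] = ~self.sel[u]
        self.cost += dcost
        self.boundary += dbound
        self.penalty += dpen
        self.held += sign * self.pu.amounts[u]

    def run(self, rng: np.random.Generator, iterations: int,
            t0: float | None, cooling: float | None) -> Solution:
        self.init_state(rng)
        avail = self.available
        if len(avail) == 0:
            return self.solution()
        if iterations < self.pu.n:
            warnings.warn("iteration budget below the number of units")
        if t0 is None:
            probes = [abs(self.delta(int(u))[0])
                      for u in rng.choice(avail, size=100)]
            t0 = float(np.percentile(probes, 90)) or 1.0
        if cooling is None:
            cooling = (1e-3) ** (1.0 / max(1, iterations))
        T = t0
        for _ in range(iterations):
            u = int(avail[rng.integers(len(avail))])
            d = self.delta(u)
            if d[0] <= 0 or rng.random() < np.exp(-d[0] / T):
                self.flip(u, d)
            T *= cooling
        # greedy descent: single flips, then two-step swaps (one unit in,
        # one out), repeated until neither finds an improving move
        improved = True
        while improved:
            improved = False
            for u in avail:
                d = self.delta(int(u))
                if d[0] < -1e-12:
                    self.flip(int(u), d)
                    improved = True
            if not improved:
                improved = self._two_step_pass()
        return self.solution()

    def _two_step_pass(self) -> bool:
        """One pass of pair exchanges; True if any improved the objective."""
        avail = self.available
        sel_in = [int(u) for u in avail if not self.sel[u]]
        sel_out = [int(u) for u in avail if self.sel[u]]
        any_improved = False
        for u in sel_in:
            du = self.delta(u)
            self.flip(u, du)
            best_v, best_dv = None, None
            for v in sel_out:
                dv = self.delta(v)
                if du[0] + dv[0] < -1e-12 and (
                        best_dv is None or dv[0] < best_dv[0]):
                    best_v, best_dv = v, dv
            if best_v is not None:
                self.flip(best_v, best_dv)
                sel_out.remove(best_v)
                sel_out.append(u)
                any_improved = True
            else:
                self.flip(u, self.delta(u))  # revert
        return any_improved

    def solution(self) -> Solution:
        return Solution(selected=self.sel.copy(), value=self.value(),
                        cost_term=self.cost,
                        boundary_term=self.blm * self.boundary,
                        penalty_term=self.penalty)


def _default_iterations(n_units: int) -> int:
    return max(2000, 50 * n_units)


def anneal(pu: PlanningUnitSet, ft: FeatureTargets, params: SAParams,
           seed: int | None = None) -> Solution:
    """One simulated-annealing run; deterministic under its seed."""
    base = base_penalties(pu, ft)
    ann = _Annealer(pu, ft, params.blm, base)
    iters = params.iterations or _default_iterations(pu.n)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return ann.run(rng, iters, params.initial_temperature, params.cooling)


def ssoln(pu: PlanningUnitSet, ft: FeatureTargets, params: SAParams
          ) -> SelectionFrequency:
    """Repeated runs -> per-unit selection frequency and best portfolio."""
    base = base_penalties(pu, ft)
    ann = _Annealer(pu, ft, params.blm, base)
    iters = params.iterations or _default_iterations(pu.n)
    counts = np.zeros(pu.n)
    best: Solution | None = None
    master = np.random.default_rng(params.seed)
    for _ in range(params.n_runs):
        rng = np.random.default_rng(int(master.integers(2**31)))
        sol = ann.run(rng, iters, params.initial_temperature, params.cooling)
        counts += sol.selected
        if best is None or sol.value < best.value:
            best = sol
    return SelectionFrequency(ssoln=counts / params.n_runs, best=best,
                              n_runs=params.n_runs)


def calibrate_blm(pu: PlanningUnitSet, ft: FeatureTargets,
                  blm_values: list[float], params: SAParams | None = None
                  ) -> pd.DataFrame:
    """BLM sensitivity sweep: cost vs boundary trade-off and its knee.

    For each BLM a short repeated-run batch reports the mean cost term
    and mean boundary length of the solutions.  The suggested BLM is the
    knee of the (boundary, cost) curve: the point with maximum
    perpendicular distance to the chord between the extreme points.
    """
    if len(blm_values) < 2:
        raise ValueError("need at least 2 BLM values")
    params = params or SAParams(n_runs=10)
    base = base_penalties(pu, ft)
    iters = params.iterations or _default_iterations(pu.n)
    rows = []
    for blm in blm_values:
        ann = _Annealer(pu, ft, float(blm), base)
        master = np.random.default_rng(params.seed)
        costs, bounds, pens = [], [], []
        for _ in range(min(params.n_runs, 20)):
            rng = np.random.default_rng(int(master.integers(2**31)))
            sol = ann.run(rng, iters, params.initial_temperature,
                          params.cooling)
            costs.append(sol.cost_term)
            bounds.append(exposed_boundary(sol.selected, pu))
            pens.append(sol.penalty_term)
        rows.append({"blm": float(blm), "mean_cost": float(np.mean(costs)),
                     "mean_boundary_km": float(np.mean(bounds)),
                     "penalty": float(np.mean(pens))})
    df = pd.DataFrame(rows)
    x = df["mean_boundary_km"].to_numpy()
    y = df["mean_cost"].to_numpy()
    xs = (x - x.min()) / (x.max() - x.min() or 1.0)
    ys = (y - y.min()) / (y.max() - y.min() or 1.0)
    p0, p1 = np.array([xs[0], ys[0]]), np.array([xs[-1], ys[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord) or 1.0
    dist = np.abs(chord[0] * (ys - p0[1]) - chord[1] * (xs - p0[0])) / norm
    df["knee_distance"] = dist
    df.attrs["suggested_blm"] = float(df.loc[dist.argmax(), "blm"])
    return df


def extract_gaps(sf: SelectionFrequency, pu: PlanningUnitSet,
                 threshold: float = 0.65) -> set[int]:
    """Available units selected in strictly more than 65% of runs."""
    flag = (sf.ssoln > threshold) & ~pu.reserved
    return set(int(i) for i in pu.ids[flag])


# ---------------------------------------------------------------------------
# Marxan-dialect flat files and GeoJSON export
# ---------------------------------------------------------------------------

def write_marxan_inputs(pu: PlanningUnitSet, ft: FeatureTargets,
                        outdir: str) -> None:
    import os
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame({"id": pu.ids, "cost": pu.costs,
                  "status": np.where(pu.reserved, 2, 0)}
                 ).to_csv(os.path.join(outdir, "pu.csv"), index=False)
    rows = [{"id1": i, "id2": j, "length": L}
            for (i, j), L in pu.boundary_matrix().items()]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "bound.csv"), index=False)
    pv = [{"unit": int(i), "feature": f, "amount": pu.amounts[i, fi]}
          for i in range(pu.n) for fi, f in enumerate(pu.feature_names)
          if pu.amounts[i, fi] > 0]
    pd.DataFrame(pv).to_csv(os.path.join(outdir, "puvfeat.csv"), index=False)
    pd.DataFrame({"feature": ft.feature_names, "target": ft.targets,
                  "spf": ft.spf}
                 ).to_csv(os.path.join(outdir, "targets.csv"), index=False)


def gaps_to_geojson(gaps: set[int], pu: PlanningUnitSet, path: str) -> None:
    feats = []
    for i in sorted(gaps):
        geom = (pu.geometries[i] if pu.geometries is not None else None)
        feats.append({
            "type": "Feature",
            "properties": {"unit_id": int(i), "cost": float(pu.costs[i])},
            "geometry": {"type": "Polygon",
                         "coordinates": geom} if geom else None,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
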