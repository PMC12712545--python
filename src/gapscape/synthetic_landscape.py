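"""Synthetic study-landscape generator.

Real inputs to this kind of analysis — field occurrence records,
provincial land-use rasters, GDP surfaces, reserve boundaries — are
rarely redistributable.  This module generates all of them with the
statistical structure the downstream pipeline assumes:

* smooth, spatially autocorrelated environmental surfaces (one of which
  plays the role of elevation),
* a categorical land-use map derived from those surfaces, evolved
  through later periods by a per-cell Markov chain (a deliberately plain
  stand-in for cellular-automata land-use simulators),
* species occurrences drawn from Gaussian niche responses,
* ancillary layers: a GDP surface coupled to construction-land density,
  blob-shaped existing reserves, and threat rasters including a
  synthetic road polyline.

Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .core_io import LANDUSE_LEGEND, Grid, LandUseMap, write_grid

# Default Markov transition matrix (rows/cols in code order 1..6:
# cropland, woodland, grassland, water, construction, unused).
# Strong persistence with a mild drift of cropland/grassland into
# construction, mimicking urbanising provincial landscapes.
DEFAULT_MARKOV = np.array([
    [0.90, 0.02, 0.02, 0.01, 0.04, 0.01],
    [0.02, 0.94, 0.02, 0.00, 0.01, 0.01],
    [0.04, 0.03, 0.88, 0.01, 0.03, 0.01],
    [0.01, 0.00, 0.01, 0.96, 0.01, 0.01],
    [0.01, 0.00, 0.00, 0.00, 0.98, 0.01],
    [0.05, 0.02, 0.03, 0.01, 0.04, 0.85],
])


@dataclass
class LandscapeScenario:
    """Parameters of one synthetic study area.

    The defaults describe the desk-scale scenario used throughout the
    package: a 120×120 grid of 1-km cells, three species with distinct
    Gaussian niches over three environmental layers, three time periods,
    10% of the area pre-reserved and GDP tightly coupled to built-up
    land.
    """

    seed: int = 1
    shape: tuple[int, int] = (120, 120)
    n_species: int = 3
    n_layers: int = 3
    periods: tuple[str, ...] = ("t0", "t1", "t2")
    points_per_species: int = 40
    niche_params: list[dict] | None = None
    markov_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_MARKOV.copy())
    gdp_coupling: float = 0.7
    reserve_fraction: float = 0.10
    cell_size_m: float = 1000.0
    smooth_sigma: float = 6.0
    jitter: bool = True
    #: probability of adopting the 4-neighbour majority class after the
    #: Markov draw (spatial contagion; 0 disables it)
    contagion: float = 0.0

    def __post_init__(self) -> None:
        self.markov_matrix = np.asarray(self.markov_matrix, dtype=float)
        if self.markov_matrix.shape != (6, 6):
            raise ValueError("markov_matrix must be 6x6")
        if not np.allclose(self.markov_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("markov_matrix rows must sum to 1")
        if np.any(self.markov_matrix < 0):
            raise ValueError("markov_matrix entries must be non-negative")
        if not 0 <= self.reserve_fraction < 1:
            raise ValueError("reserve_fraction must be in [0, 1)")
        if self.niche_params is None:
            self.niche_params = self._default_niches()
        for sp in self.niche_params:
            if np.any(np.asarray(sp["breadth"], dtype=float) <= 0):
                raise ValueError("niche breadths must be positive")

    def _default_niches(self) -> list[dict]:
        # Deterministic spread of optima over standardized layer space.
        # Narrow breadths emulate rare, habitat-specialist protected
        # plants whose occurrences concentrate in small environmental
        # envelopes of a large province.
        rng = np.random.default_rng(self.seed + 7919)
        out = []
        for s in range(self.n_species):
            opt = rng.uniform(-1.0, 1.0, size=self.n_layers)
            breadth = rng.uniform(0.2, 0.4, size=self.n_layers)
            out.append({"species": f"species_{s + 1}",
                        "optimum": opt.tolist(), "breadth": breadth.tolist()})
        return out

    @property
    def species_names(self) -> list[str]:
        return [sp["species"] for sp in self.niche_params]


def _rng(scenario: LandscapeScenario, salt: int) -> np.random.Generator:
    return np.random.default_rng((scenario.seed, salt))


def make_environment(scenario: LandscapeScenario) -> list[Grid]:
    """Generate smooth standardized environmental surfaces.

    Each surface is low-pass-filtered white noise plus a weak linear
    trend, standardized to mean 0 and sd 1 over the grid.  The first
    surface is treated as elevation by downstream land-use seeding.
    Lag-1 neighbour correlation exceeds 0.5 at the default smoothing.
    """
    rows, cols = scenario.shape
    if rows < 20 or cols < 20:
        raise ValueError("grid must be at least 20x20 for windowed metrics")
    rng = _rng(scenario, 1)
    yy, xx = np.mgrid[0:rows, 0:cols]
    out = []
    for i in range(max(3, scenario.n_layers)):
        noise = rng.standard_normal((rows, cols))
        smooth = ndimage.gaussian_filter(noise, sigma=scenario.smooth_sigma)
        trend_dir = rng.uniform(0, 2 * np.pi)
        trend = (np.cos(trend_dir) * xx / cols + np.sin(trend_dir) * yy / rows)
        surf = smooth / smooth.std() + 0.5 * trend
        surf = (surf - surf.mean()) / surf.std()
        out.append(Grid(values=surf, cell_size_m=scenario.cell_size_m,
                        crs_label="synthetic-albers"))
    return out


def _initial_landuse(scenario: LandscapeScenario, environment: list[Grid],
                     rng: np.random.Generator) -> np.ndarray:
    """Seed period-0 land use by thresholding environmental surfaces."""
    elev = environment[0].values
    wet = environment[1].values if len(environment) > 1 else -elev
    rows, cols = elev.shape
    lu = np.full((rows, cols), 3, dtype=np.int64)  # grassland background
    lu[elev > np.quantile(elev, 0.55)] = 2          # high ground: woodland
    low_flat = elev < np.quantile(elev, 0.45)
    lu[low_flat] = 1                                # lowlands: cropland
    lu[(wet > np.quantile(wet, 0.93)) & low_flat] = 4   # wet lowlands: water
    # construction kernels: a few seeded towns in the lowlands, grown by
    # dilation so built-up land is clumped
    n_towns = max(2, rows * cols // 4000)
    town = np.zeros_like(lu, dtype=bool)
    flat_idx = np.flatnonzero(low_flat)
    seeds = rng.choice(flat_idx, size=min(n_towns, flat_idx.size), replace=False)
    town.ravel()[seeds] = True
    town = ndimage.binary_dilation(town, iterations=max(2, rows // 40))
    lu[town] = 5
    # scattered unused land on the driest high cells
    dry = elev > np.quantile(elev, 0.97)
    lu[dry] = 6
    return lu


def make_landuse_series(scenario: LandscapeScenario,
                        environment: list[Grid]) -> list[LandUseMap]:
    """Land-use maps per period: thresholded seed, then Markov transitions.

    Each later period redraws every cell from the transition row of its
    previous class; class proportions drift toward the chain's
    stationary distribution as periods accumulate.
    """
    P = scenario.markov_matrix
    rng = _rng(scenario, 2)
    lu = _initial_landuse(scenario, environment, rng)
    geom = environment[0]
    series = [LandUseMap(grid=geom.like(lu))]
    cum = np.cumsum(P, axis=1)
    for _ in scenario.periods[1:]:
        u = rng.random(lu.shape)
        nxt = np.empty_like(lu)
        for code in range(1, 7):
            sel = lu == code
            if sel.any():
                nxt[sel] = 1 + np.searchsorted(cum[code - 1], u[sel], side="right")
        nxt = np.clip(nxt, 1, 6)
        if scenario.contagion > 0:
            nxt = _apply_contagion(nxt, scenario.contagion, rng)
        lu = nxt
        series.append(LandUseMap(grid=geom.like(lu.copy())))
    return series


def _apply_contagion(lu: np.ndarray, strength: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Adopt the strict 4-neighbour majority class with probability
    ``strength`` (clumps land use, mimicking contagious change)."""
    rows, cols = lu.shape
    counts = np.zeros((6, rows, cols), dtype=np.int8)
    for code in range(1, 7):
        m = (lu == code).astype(np.int8)
        counts[code - 1] = (np.roll(m, 1, 0) + np.roll(m, -1, 0)
                            + np.roll(m, 1, 1) + np.roll(m, -1, 1))
    majority = counts.argmax(axis=0) + 1
    has_majority = counts.max(axis=0) >= 3
    adopt = has_majority & (rng.random(lu.shape) < strength)
    out = lu.copy()
    out[adopt] = majority[adopt]
    return out


def true_suitability(scenario: LandscapeScenario, environment: list[Grid],
                     species: str) -> Grid:
    """The generating niche probability surface for one species.

    Product of Gaussian responses exp(-(e - opt)^2 / (2 b^2)) over the
    environmental layers, scaled to max 1.
    """
    sp = next(s for s in scenario.niche_params if s["species"] == species)
    opt = np.asarray(sp["optimum"], dtype=float)
    br = np.asarray(sp["breadth"], dtype=float)
    prob = np.ones(scenario.shape)
    for j in range(len(opt)):
        e = environment[j].values
        prob *= np.exp(-((e - opt[j]) ** 2) / (2.0 * br[j] ** 2))
    prob /= prob.max()
    return environment[0].like(prob)


def make_occurrences(scenario: LandscapeScenario,
                     environment: list[Grid]) -> pd.DataFrame:
    """Sample species occurrence points from the niche surfaces.

    Cells are drawn without replacement with probability proportional to
    the niche response; by default point coordinates are jittered
    uniformly within the cell, so several points can fall within the
    1-km thinning radius of each other and the thinning step has work
    to do.

    Returns a DataFrame with columns species, x, y.
    """
    rng = _rng(scenario, 3)
    geom = environment[0]
    rows = []
    for sp in scenario.niche_params:
        prob = true_suitability(scenario, environment, sp["species"]).values.ravel()
        n = scenario.points_per_species
        positive = np.flatnonzero(prob > 0)
        if n > positive.size:
            raise ValueError(
                f"{sp['species']}: requested {n} points but only "
                f"{positive.size} cells have positive probability")
        p = prob / prob.sum()
        cells = rng.choice(prob.size, size=n, replace=False, p=p)
        r, c = np.unravel_index(cells, scenario.shape)
        if scenario.jitter:
            dx = rng.uniform(-0.5, 0.5, size=n)
            dy = rng.uniform(-0.5, 0.5, size=n)
        else:
            dx = dy = np.zeros(n)
        for i in range(n):
            cx, cy = geom.cell_center(int(r[i]), int(c[i]))
            rows.append({"species": sp["species"],
                         "x": cx + dx[i] * geom.cell_size_m,
                         "y": cy + dy[i] * geom.cell_size_m})
    return pd.DataFrame(rows, columns=["species", "x", "y"])


def _blob_mask(shape: tuple[int, int], fraction: float,
               rng: np.random.Generator) -> np.ndarray:
    """Random smooth blobs covering ``fraction`` (±0.02) of the cells."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=7)
    thr = np.quantile(noise, 1.0 - fraction)
    return noise > thr


def _road_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """A 1-cell-wide connected polyline crossing the grid."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    r = int(rng.integers(rows // 4, 3 * rows // 4))
    c = 0
    mask[r, c] = True
    while c < cols - 1:
        step = rng.choice([-1, 0, 0, 1])
        nr = int(np.clip(r + step, 0, rows - 1))
        if nr != r:
            mask[nr, c] = True  # keep rook connectivity on diagonal moves
            r = nr
        c += 1
        mask[r, c] = True
    return mask


def make_ancillary(scenario: LandscapeScenario, landuse: LandUseMap) -> dict:
    """GDP, existing-reserve mask, and threat-source rasters.

    GDP is a smoothed construction-density surface times positive
    log-normal noise, with Pearson correlation to construction density
    of at least ``gdp_coupling``; reserves are random blobs; threats are
    the cropland mask, the construction mask, and one synthetic road.
    """
    rng = _rng(scenario, 4)
    geom = landuse.grid
    constr = (landuse.grid.values == 5).astype(float)
    density = ndimage.gaussian_filter(constr, sigma=3)
    noise = np.exp(0.25 * rng.standard_normal(geom.shape))
    gdp = (0.05 + density) * noise
    # blend toward pure density until coupling target is met
    for _ in range(20):
        r = np.corrcoef(gdp.ravel(), density.ravel())[0, 1]
        if r >= scenario.gdp_coupling:
            break
        gdp = 0.5 * gdp + 0.5 * (0.05 + density) * gdp.mean() / (0.05 + density).mean()
    reserves = _blob_mask(geom.shape, scenario.reserve_fraction, rng)
    threats = {
        "cropland": geom.like((landuse.grid.values == 1).astype(float)),
        "construction": geom.like(constr),
        "road": geom.like(_road_mask(geom.shape, rng).astype(float)),
    }
    return {"gdp": geom.like(gdp), "reserves": geom.like(reserves),
            "threats": threats}


def generate_scenario(scenario: LandscapeScenario) -> dict:
    """Run all four generators; returns a dict of every synthetic input."""
    env = make_environment(scenario)
    landuse = make_landuse_series(scenario, env)
    occ = make_occurrences(scenario, env)
    anc = make_ancillary(scenario, landuse[0])
    truth = {sp: true_suitability(scenario, env, sp)
             for sp in scenario.species_names}
    return {"environment": env, "landuse": landuse, "occurrences": occ,
            "gdp": anc["gdp"], "reserves": anc["reserves"],
            "threats": anc["threats"], "truth": truth, "scenario": scenario}


def write_scenario(data: dict, outdir: str, fmt: str = "asc") -> list[str]:
    """Write a generated scenario to a directory; returns written paths."""
    os.makedirs(outdir, exist_ok=True)
    sc: LandscapeScenario = data["scenario"]
    paths = []

    def _w(grid: Grid, name: str) -> None:
        p = os.path.join(outdir, f"{name}.{fmt}")
        write_grid(grid, p)
        paths.append(p)

    for i, g in enumerate(data["environment"]):
        _w(g, f"env_{i}")
    for period, lum in zip(sc.periods, data["landuse"]):
        _w(lum.grid, f"landuse_{period}")
    _w(data["gdp"], "gdp")
    _w(Grid(values=data["reserves"].values.astype(np.int32),
            cell_size_m=sc.cell_size_m), "reserves")
    for name, g in data["threats"].items():
        _w(g, f"threat_{name}")
    for sp, g in data.get("truth", {}).items():
        _w(g, f"truth_{sp}")
    occ_path = os.path.join(outdir, "occurrences.csv")
    data["occurrences"].to_csv(occ_path, index=False)
    paths.append(occ_path)
    meta = {
        "seed": sc.seed, "shape": list(sc.shape), "n_species": sc.n_species,
        "periods": list(sc.periods), "points_per_species": sc.points_per_species,
        "niche_params": sc.niche_params,
        "markov_matrix": sc.markov_matrix.tolist(),
        "gdp_coupling": sc.gdp_coupling, "reserve_fraction": sc.reserve_fraction,
        "cell_size_m": sc.cell_size_m, "legend": LANDUSE_LEGEND,
    }
    yml = os.path.join(outdir, "scenario.yaml")
    with open(yml, "w") as fh:
        yaml.safe_dump(meta, fh)
    paths.append(yml)
    return paths
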