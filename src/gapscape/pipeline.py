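"""End-to-end orchestration of the conservation-gap analysis.

Stages run in dependency order for each time period:

    generate -> hq -> carbon -> sdm -> clfi -> hdi -> prioritize
             -> overlay -> gaps

Every stage persists its artifacts (text rasters, CSV/JSON summaries)
under the output directory, so stages can also be run one at a time
from the command line; ``run_all`` executes them all and writes a
manifest with a SHA-256 digest of every artifact.  One global seed fans
out to stage-specific seeds by stable hashing of stage names, so adding
a stage never perturbs the randomness of earlier ones.  Re-running with
the same configuration and seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (carbon_stock, cost_hdi, fragmentation, habitat_quality,
               overlay_gap, prioritizer, sdm_ensemble, synthetic_landscape)
from .core_io import Grid, LandUseMap, read_grid, write_grid

logger = logging.getLogger("gapscape")

STAGES = ["generate", "hq", "carbon", "sdm", "clfi", "hdi",
          "prioritize", "overlay", "gaps"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class PipelineConfig:
    outdir: str = "gapscape_out"
    seed: int = 1
    # synthetic scenario
    shape: tuple[int, int] = (120, 120)
    n_species: int = 3
    periods: tuple[str, ...] = ("t0", "t1", "t2")
    points_per_species: int = 40
    reserve_fraction: float = 0.10
    gdp_coupling: float = 0.7
    # module parameters
    thin_radius_km: float = 1.0
    r_max: float = 0.8
    ensemble_runs: int = 10
    n_background: int = 500
    inclusion_threshold: float = 0.8
    window_size: int = 20
    block_size: int = 10
    n_runs: int = 100
    sa_iterations: int | None = None
    blm: float = 0.001
    target_fraction: float = 0.3
    spf_species: float = 5.0
    spf_other: float = 3.0
    gap_threshold: float = 0.65
    carbon_top_k: int = 2
    hq_change_tol: float = 0.01

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["periods"] = list(self.periods)
        return d


class Pipeline:
    """Stateful runner; stages reload prerequisites from disk if absent."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.state: dict = {}
        self.artifacts: list[str] = []
        os.makedirs(config.outdir, exist_ok=True)

    # -- helpers ---------------------------------------------------------
    def _dir(self, stage: str) -> str:
        d = os.path.join(self.cfg.outdir, stage)
        os.makedirs(d, exist_ok=True)
        return d

    def _write_grid(self, grid: Grid, stage: str, name: str) -> str:
        p = os.path.join(self._dir(stage), f"{name}.asc")
        write_grid(grid, p)
        self.artifacts.append(p)
        return p

    def _write_json(self, obj, stage: str, name: str) -> str:
        p = os.path.join(self._dir(stage), f"{name}.json")
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
        self.artifacts.append(p)
        return p

    def _write_csv(self, df: pd.DataFrame, stage: str, name: str) -> str:
        p = os.path.join(self._dir(stage), f"{name}.csv")
        df.to_csv(p, index=False)
        self.artifacts.append(p)
        return p

    def _scenario(self) -> dict:
        if "scenario_data" not in self.state:
            self.stage_generate()
        return self.state["scenario_data"]

    # -- stages ----------------------------------------------------------
    def stage_generate(self) -> None:
        cfg = self.cfg
        sc = synthetic_landscape.LandscapeScenario(
            seed=stage_seed(cfg.seed, "generate"), shape=tuple(cfg.shape),
            n_species=cfg.n_species, periods=tuple(cfg.periods),
            points_per_species=cfg.points_per_species,
            reserve_fraction=cfg.reserve_fraction,
            gdp_coupling=cfg.gdp_coupling)
        data = synthetic_landscape.generate_scenario(sc)
        paths = synthetic_landscape.write_scenario(
            data, os.path.join(cfg.outdir, "scenario"))
        self.artifacts.extend(paths)
        self.state["scenario_data"] = data
        logger.info("generate: %d layers, %d species, %d periods",
                    len(data["environment"]), cfg.n_species, len(cfg.periods))

    def stage_hq(self) -> None:
        data = self._scenario()
        cfg = self.cfg
        sens = habitat_quality.default_sensitivity()
        results = {}
        for period, lum in zip(cfg.periods, data["landuse"]):
            sources = {
                "cropland": lum.mask_of("cropland"),
                "construction": lum.mask_of("construction"),
                "road": data["threats"]["road"],
            }
            sources = {k: v.like(np.asarray(v.values, dtype=float))
                       for k, v in sources.items()}
            threats = habitat_quality.default_threats(sources)
            D = habitat_quality.degradation(threats, sens, lum)
            res = habitat_quality.quality(D, lum, sens)
            results[period] = res
            self._write_grid(res.quality, "hq", f"quality_{period}")
            self._write_grid(res.classes, "hq", f"quality_class_{period}")
            self._write_json(res.summary(), "hq", f"summary_{period}")
        first, last = cfg.periods[0], cfg.periods[-1]
        change = habitat_quality.hq_change(results[first].quality,
                                           results[last].quality,
                                           tol=cfg.hq_change_tol)
        self._write_json({k: v for k, v in change.items() if k != "change"},
                         "hq", "change")
        self.state["hq"] = results

    def stage_carbon(self) -> None:
        data = self._scenario()
        cfg = self.cfg
        table = carbon_stock.CarbonDensityTable.default()
        results = {}
        for period, lum in zip(cfg.periods, data["landuse"]):
            res = carbon_stock.carbon_map(lum, table)
            results[period] = res
            self._write_grid(res.zones, "carbon", f"zones_{period}")
            self._write_json(res.summary(), "carbon", f"summary_{period}")
        delta = carbon_stock.carbon_change(results[cfg.periods[0]],
                                           results[cfg.periods[-1]])
        self._write_json({"delta_total_t": delta["delta_total_t"]},
                         "carbon", "change")
        self.state["carbon"] = results

    def stage_sdm(self) -> None:
        data = self._scenario()
        cfg = self.cfg
        seed = stage_seed(cfg.seed, "sdm")
        geom = data["environment"][0].like(
            np.zeros(data["environment"][0].shape))
        occ = sdm_ensemble.thin_table(data["occurrences"],
                                      radius_km=cfg.thin_radius_km, seed=seed)
        results: dict[str, dict] = {}
        for pi, (period, lum) in enumerate(zip(cfg.periods, data["landuse"])):
            ehp = fragmentation.ehp_covariates(lum, cfg.window_size)
            layers = list(data["environment"]) + ehp
            per_species = {}
            for si, sp in enumerate(sorted(occ["species"].unique())):
                pts = occ.loc[occ["species"] == sp, ["x", "y"]].to_numpy()
                cells = np.unique(
                    sdm_ensemble.points_to_cells(pts, geom), axis=0)
                flt, _ = sdm_ensemble.filter_predictors(layers, pts,
                                                        r_max=cfg.r_max)
                model, surf = sdm_ensemble.ensemble(
                    sp, cells, flt, runs=cfg.ensemble_runs,
                    seed=seed + 1000 * pi + si,
                    n_background=cfg.n_background,
                    inclusion_threshold=cfg.inclusion_threshold)
                per_species[sp] = (model, surf)
                self._write_grid(surf.p_ens, "sdm", f"p_ens_{sp}_{period}")
                self._write_grid(surf.high_mask.like(
                    surf.high_mask.values.astype(np.int32)),
                    "sdm", f"high_{sp}_{period}")
            stack = sdm_ensemble.stack_richness(
                [surf for _, surf in per_species.values()])
            self._write_grid(stack["richness"], "sdm", f"richness_{period}")
            self._write_csv(sdm_ensemble.evaluation_table(per_species),
                            "sdm", f"evaluation_{period}")
            results[period] = {"species": per_species, "stack": stack}
        self.state["sdm"] = results

    def stage_clfi(self) -> None:
        data = self._scenario()
        cfg = self.cfg
        sdm = self.state.get("sdm")
        hq = self.state.get("hq")
        if sdm is None or hq is None:
            raise RuntimeError("clfi stage needs sdm and hq results")
        out = {}
        for family, masks in (
            ("species", {p: overlay_gap.species_union_mask(
                [s.high_mask for _, s in sdm[p]["species"].values()])
                for p in cfg.periods}),
            ("habitat", {p: hq[p].high_value_mask for p in cfg.periods}),
        ):
            res = fragmentation.clfi(masks, cfg.window_size)
            out[family] = res
            for period, r in res.items():
                self._write_grid(r.grid, "clfi", f"clfi_{family}_{period}")
            self._write_json({p: r.mean_clfi for p, r in res.items()},
                             "clfi", f"mean_{family}")
        self.state["clfi"] = out

    def stage_hdi(self) -> None:
        data = self._scenario()
        cfg = self.cfg
        results = {}
        for period, lum in zip(cfg.periods, data["landuse"]):
            ind = cost_hdi.IndicatorSet(
                names=["gdp", "landuse"],
                grids=[data["gdp"], cost_hdi.landuse_disturbance(lum)])
            w = cost_hdi.entropy_weights(ind)
            surface = cost_hdi.hdi(ind, w)
            results[period] = {"weights": w, "hdi": surface}
            self._write_grid(surface, "hdi", f"hdi_{period}")
            self._write_json({n: float(x) for n, x in
                              zip(w.names, w.weights)}, "hdi",
                             f"weights_{period}")
        self.state["hdi"] = results

    def _feature_masks(self, period: str) -> dict[str, Grid]:
        sdm = self.state["sdm"][period]
        hq = self.state["hq"][period]
        carbon = self.state["carbon"][period]
        masks = {f"species:{sp}": surf.high_mask
                 for sp, (_, surf) in sdm["species"].items()}
        masks["habitat_high"] = hq.high_value_mask
        masks["carbon_high"] = overlay_gap.carbon_high_mask(
            carbon.zones, self.cfg.carbon_top_k)
        return masks

    def stage_prioritize(self) -> None:
        data = self._scenario()
        cfg = self.cfg
        for req in ("sdm", "hq", "carbon", "hdi"):
            if req not in self.state:
                raise RuntimeError(f"prioritize stage needs {req} results")
        seed = stage_seed(cfg.seed, "prioritize")
        results = {}
        for period in cfg.periods:
            masks = self._feature_masks(period)
            pu = prioritizer.build_units(
                self.state["hdi"][period]["hdi"], masks, data["reserves"],
                block_size=cfg.block_size)
            spf = np.array([cfg.spf_species if n.startswith("species:")
                            else cfg.spf_other for n in pu.feature_names])
            ft = prioritizer.FeatureTargets.proportional(
                pu, cfg.target_fraction, spf)
            params = prioritizer.SAParams(
                blm=cfg.blm, n_runs=cfg.n_runs,
                iterations=cfg.sa_iterations, seed=seed)
            sf = prioritizer.ssoln(pu, ft, params)
            results[period] = {"pu": pu, "ft": ft, "sf": sf}
            self._write_csv(pd.DataFrame(
                {"id": pu.ids, "ssoln": sf.ssoln,
                 "best": sf.best.selected.astype(int),
                 "reserved": pu.reserved.astype(int)}),
                "prioritize", f"ssoln_{period}")
            self._write_json(
                {"best_value": sf.best.value,
                 "cost_term": sf.best.cost_term,
                 "boundary_term": sf.best.boundary_term,
                 "penalty_term": sf.best.penalty_term},
                "prioritize", f"best_{period}")
        self.state["prioritize"] = results

    def stage_overlay(self) -> None:
        cfg = self.cfg
        for req in ("sdm", "hq", "carbon"):
            if req not in self.state:
                raise RuntimeError(f"overlay stage needs {req} results")
        results = {}
        for period in cfg.periods:
            masks = self._feature_masks(period)
            species_union = overlay_gap.species_union_mask(
                [m for n, m in masks.items() if n.startswith("species:")])
            om = overlay_gap.overlay(species_union, masks["habitat_high"],
                                     masks["carbon_high"])
            results[period] = om
            self._write_grid(om.categories, "overlay", f"overlay_{period}")
            self._write_json(om.shares, "overlay", f"shares_{period}")
        self.state["overlay"] = results

    def stage_gaps(self) -> None:
        cfg = self.cfg
        if "prioritize" not in self.state:
            raise RuntimeError("gaps stage needs prioritize results")
        per_period = {}
        for period in cfg.periods:
            r = self.state["prioritize"][period]
            gaps = prioritizer.extract_gaps(r["sf"], r["pu"],
                                            cfg.gap_threshold)
            per_period[period] = gaps
            p = os.path.join(self._dir("gaps"), f"gaps_{period}.geojson")
            prioritizer.gaps_to_geojson(gaps, r["pu"], p)
            self.artifacts.append(p)
        gs = overlay_gap.persistent_gaps(per_period)
        p0 = cfg.periods[0]
        p = os.path.join(self._dir("gaps"), "persistent_gaps.geojson")
        prioritizer.gaps_to_geojson(gs.persistent,
                                    self.state["prioritize"][p0]["pu"], p)
        self.artifacts.append(p)
        self._write_json({"per_period": {k: sorted(v) for k, v in
                                         gs.per_period.items()},
                          "per_period_counts": gs.per_period_counts,
                          "persistent": sorted(gs.persistent),
                          "persistent_count": len(gs.persistent)},
                         "gaps", "summary")
        self.state["gaps"] = gs

    # -- orchestration ---------------------------------------------------
    def run_all(self) -> dict:
        stage_fns = {
            "generate": self.stage_generate, "hq": self.stage_hq,
            "carbon": self.stage_carbon, "sdm": self.stage_sdm,
            "clfi": self.stage_clfi, "hdi": self.stage_hdi,
            "prioritize": self.stage_prioritize,
            "overlay": self.stage_overlay, "gaps": self.stage_gaps,
        }
        completed = []
        for name in STAGES:
            logger.info("stage %s ...", name)
            try:
                stage_fns[name]()
            except Exception as exc:
                partial = os.path.join(self.cfg.outdir,
                                       "manifest.partial.json")
                with open(partial, "w") as fh:
                    json.dump(self._manifest(completed), fh, indent=2,
                              sort_keys=True)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            completed.append(name)
        manifest = self._manifest(completed)
        mpath = os.path.join(self.cfg.outdir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    def _manifest(self, completed: list[str]) -> dict:
        arts = []
        for p in sorted(set(self.artifacts)):
            with open(p, "rb") as fh:
                digest = hashlib.sha256(fh.read()).hexdigest()
            arts.append({"path": os.path.relpath(p, self.cfg.outdir),
                         "sha256": digest})
        return {"config": self.cfg.to_dict(), "stages": completed,
                "artifacts": arts}


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest."""
    return Pipeline(config).run_all()
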