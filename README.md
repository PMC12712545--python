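# gapscape

Multi-perspective conservation-gap analysis for regional landscapes:
where should new protected areas go so that threatened species, intact
habitat, and carbon stores are all covered — now and under future land
use?

`gapscape` re-implements, as a tested and reusable Python pipeline, a
workflow widely used in systematic conservation planning for provincial
study areas:

1. **Habitat quality** — an InVEST-style model scores every cell of a
   categorical land-use map by its habitat suitability `H_j` and its
   threat-driven degradation `D`, combined through a half-saturation
   transform
   `Q = H_j · (1 − D^z / (D^z + k^z))` with `z = 2.5` and `k` set to
   half the maximum degradation. Quality is valued on five
   equal-interval levels; the top two form the high-value habitat mask.
2. **Carbon stock** — per-class carbon densities (above- and
   below-ground biomass, soil, dead matter; t/ha) give per-cell
   densities and the landscape total `C = Σ_i c_i · R_i`, zoned into
   six natural-breaks categories.
3. **Species distribution ensemble** — occurrences are cleaned and
   spatially thinned (1 km), collinear predictors filtered
   (|r| > 0.8), member models fit over repeated 75/25 splits with 500
   background points, and members with TSS > 0.8 combined as
   `P = Σ ω_i P_i` with `ω_i ∝ TSS_i`. The ensemble is binarized at its
   max-TSS threshold, classed by Jenks breaks, and stacked into species
   richness. A surface-range envelope and a quadratic ridge-logistic
   GLM are built in; predictions from external algorithms can join the
   ensemble.
4. **Fragmentation** — per-window patch metrics NP, PD, AREA_MN and the
   aggregation index AI combine into the Composite Landscape
   Fragmentation Index, `CLFI = (NP' + PD' + AREA_MN* + AI*) / 4`,
   where `'` is min-max normalization and `*` its inversion.
5. **Cost and prioritization** — GDP and land-use disturbance are
   combined by the entropy weight method into a Human Disturbance
   Index, the cost surface for Marxan-style reserve selection:
   `value = Σ cost + BLM · boundary + Σ SPF_f · penalty_f`, optimized
   by simulated annealing; 100 repeated runs give per-unit selection
   frequencies (ssoln).
6. **Gaps** — available units with ssoln > 65% are conservation gaps;
   the species/habitat/carbon masks are overlaid into eight priority
   categories; gaps recurring in every period are proposed future
   conservation areas.

Because real occurrence records and provincial rasters of such studies
are rarely redistributable, a first-class synthetic-landscape module
generates all inputs with the statistical structure the pipeline
assumes (autocorrelated environments, Gaussian-niche occurrences,
Markov land-use change, GDP coupled to built-up land, blob reserves),
fully deterministic under one seed.

## Worked example

```python
from gapscape import PipelineConfig, run_all

manifest = run_all(PipelineConfig(outdir="demo", seed=1))
print(len(manifest["artifacts"]), "artifacts")
```

This runs the full analysis on the default synthetic province
(120 × 120 km at 1-km resolution, 3 species, 3 periods) in about two
minutes and writes text rasters plus JSON/CSV summaries per stage. With
seed 1 the run reports, among others:

```
hq/summary_t0.json      mean_hqi = 0.672
hq/summary_t2.json      mean_hqi = 0.571
carbon/summary_t0.json  total_C_t = 2.07e8
sdm/evaluation_t0.csv   ensemble AUC ≈ 0.98, member TSS ≈ 0.91 per species
hdi/weights_t0.json     gdp 0.247, landuse 0.753
gaps/summary.json       27 / 26 / 20 gap units per period, 22 persistent
```

i.e. habitat quality declines as construction expands through the
Markov land-use projection, carbon stock falls with it, the ensembles
recover the planted niches with high skill, and 22 planning units
remain unprotected high-priority gaps in every period — the map
products (quality classes, carbon zones, richness, CLFI, overlay
categories, gap GeoJSONs) are in the output directory.

Equivalent shell interface:

```sh
gapscape --outdir demo --seed 1 run-all
gapscape --outdir demo --seed 1 sdm      # any single stage + prerequisites
```

## Layout

```
src/gapscape/
  core_io.py             Grid model, ASCII/TIFF I/O, equal-interval + Jenks
  synthetic_landscape.py scenario generator (environments, land use,
                         occurrences, GDP/reserves/threats)
  habitat_quality.py     threat impacts, degradation, half-saturation quality
  carbon_stock.py        density tables, totals, natural-breaks zoning
  sdm_ensemble.py        thinning, predictor filtering, members, metrics,
                         TSS-weighted ensemble, richness stacking
  fragmentation.py       patch metrics, AI, CLFI, EHP covariates
  cost_hdi.py            entropy weights, HDI cost surface
  overlay_gap.py         8-category overlay, persistent gaps
  prioritizer.py         planning units, objective, annealer, ssoln, BLM
  pipeline.py / cli.py   orchestration, YAML config, click CLI
```

See `docs/methods.md` for the model descriptions, parameter defaults,
and the design choices behind under-specified steps.
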