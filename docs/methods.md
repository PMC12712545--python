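# Methods

This note documents the models implemented in `gapscape`, their
assumptions, the parameters that matter, and the choices made where the
underlying methods are under-specified in common usage.

## Spatial data model

All layers are single-band, north-up rasters (`Grid`): a value array, a
nodata mask, a cell size in meters (default 1000 m, so one cell is
1 km² = 100 ha) and a top-left origin. Layers in one analysis are
assumed pre-aligned; no reprojection or resampling is performed. The
interchange formats are the ESRI ASCII grid (text, with a `.prj`
sidecar for the CRS label) and single-band TIFF with
ModelPixelScale/ModelTiepoint tags. Land use is categorical over six
classes: cropland, woodland, grassland, water, construction, unused
(codes 1–6).

Classification uses half-open, lower-inclusive intervals
`[e_i, e_{i+1})`, with the global maximum closed into the top class;
the bin edges of published level schemes ("0.8–1", "0.6–0.8", …) do
not state edge ownership, so the convention is fixed here once.
Natural-breaks classification is exact Fisher–Jenks dynamic
programming on distinct values weighted by multiplicity (ties are
never split; deterministic), not a k-means heuristic.

## Synthetic landscape

The generator produces every input a real application would obtain
from surveys and public rasters, with the statistical structure the
pipeline assumes — it emulates structure, not any real geography.

* **Environments**: Gaussian-filtered white noise (σ = 6 cells) plus a
  weak directional trend, standardized to mean 0/sd 1; lag-1 neighbour
  correlation > 0.5. The first surface plays the role of elevation.
* **Land use**: period 0 by thresholding the surfaces (uplands →
  woodland, lowlands → cropland, wet lowlands → water, dilated town
  seeds → construction); later periods by per-cell draws from a
  6 × 6 row-stochastic Markov matrix whose default drifts cropland and
  grassland mildly toward construction. A cellular-automata allocator
  is deliberately not emulated: the pipeline needs plausible
  multi-period maps, not a land-use model.
* **Occurrences**: per species, cells are drawn without replacement
  with probability proportional to a product of Gaussian responses
  `exp(−(e − opt)² / 2b²)` over the layers; points are jittered
  uniformly within their cell so that 1-km thinning has work to do.
  Default 40 points per species (above the ≈ 30-record floor common
  in distribution modelling practice).
* **Niche breadths** default to uniform(0.2, 0.4) on the standardized
  layers — strong habitat specialists. This is deliberate: the
  ensemble's member-inclusion rule (TSS > 0.8) presumes sharply
  separable species; with broad generalist niches even the *true*
  probability surface cannot reach TSS 0.8 against a uniform
  background, and the workflow is undefined regardless of model skill.
  Threatened, narrowly distributed plants are exactly the species this
  kind of analysis targets.
* **Ancillary**: GDP is smoothed construction density × log-normal
  noise, blended until its correlation with construction density
  reaches the coupling target (default 0.7); reserves are smooth random
  blobs covering the requested fraction (default 10%); threat sources
  are the cropland mask, the construction mask, and a 1-cell-wide
  random road polyline.

What the generator does **not** emulate: real climate fields, spatial
sampling bias in occurrence records, label noise in land-use maps,
administrative-boundary planning units, and spatially contiguous
land-use change. Tests passing on this generator therefore demonstrate
correctness of the computations and recoverability under clean
conditions, not performance on real survey data.

## Habitat quality

Threat impact at a cell is the decay-weighted mean over source cells
within the threat's maximum distance: linear `1 − d/d_max` or
exponential `exp(−2.99 d / d_max)` (≈ 0.05 at `d_max`), divided by the
number of contributing source cells so impact stays in [0, 1].
Degradation weights threats by `w_r / Σw`, scales by the land-use
class's sensitivity `S_{j,r} ∈ [0, 1]` and by per-cell accessibility
`β ∈ [0, 1]` (default 1). Quality applies the half-saturation
transform with `z = 2.5` and `k = max(D)/2` by default (`k = 0.5`
when nothing is degraded, leaving `Q = H`). Degradation is defined on
non-habitat cells too; the habitat score zeroes their quality.

The packaged threat table (cropland w = 0.6, 1 km, linear;
construction w = 1.0, 8 km, exponential; road w = 0.7, 2 km, linear)
and the sensitivity/habitat-score table are literature-typical values
for a six-class provincial landscape and are fully overridable via
YAML/CSV; no acceptance check depends on them. Change maps use a
tolerance of 0.01 so floating-point churn is not counted as change.

## Carbon stock

Per-class densities are the sum of four pools (t/ha). The landscape
total is computed class-wise (`Σ c_i · R_i`, areas in ha), which equals
the per-cell sum exactly up to summation order. Zoning applies Jenks
k = 5 over the distinct positive densities plus a dedicated zero
("none") class; with fewer than five distinct positive densities the
zones collapse top-down (the high zones are kept). Zoning operates on
per-cell density, not windowed totals. The packaged density table is
literature-typical and overridable.

## Distribution models and ensemble

* **Thinning**: exact duplicates removed, then a seeded random visiting
  order keeps each point only if no kept point lies within the radius
  (default 1 km) — randomized removal, reproducible under the seed.
* **Predictor filtering**: greedy — while any pair of layers has
  |Pearson r| > 0.8 over valid cells, drop the member of the worst pair
  with the lower absolute point-biserial correlation against
  presence/background labels.
* **Members**: a surface-range envelope (fraction of layers inside the
  [2.5%, 97.5%] presence quantile interval) and a ridge-penalized
  logistic regression on standardized layers *with quadratic terms*, so
  unimodal niches are representable — the conventional polynomial GLM
  of ensemble platforms. The ridge default is l2 = 0.1: with a handful
  of predictors and a few hundred training points a light penalty
  stabilizes the fit without the visible shrinkage bias of heavier
  regularization. External prediction rasters (range-checked,
  alignment-checked) can join the ensemble and are re-scored on the
  held-out points.
* **Evaluation**: AUC by the rank statistic with midranks; TSS by an
  exact sweep over the unique predicted score values with the
  `score ≥ threshold` decision rule; TSS ties break toward the lower
  threshold (the larger predicted suitable area); kappa at the max-TSS
  threshold.
* **Ensemble**: per run the presences and a fresh 500-point uniform
  background sample are resplit 75/25 and members refit; member skill
  is the mean TSS over the 10 runs (averaging, not pooling — the
  common ensemble-platform behaviour); members above TSS 0.8 enter the
  weighted mean with `ω ∝ TSS`. Probabilities are ensembled first and
  the ensemble binarized at its own max-TSS threshold computed on the
  pooled held-out points (not: binarize members first). Above-threshold
  suitabilities are split low/medium/high by Jenks; the high class
  alone feeds richness stacking and the overlay (richness bins:
  0 / 1–2 / 3–4 / 5–6 / ≥ 7 species).

## Fragmentation

Patches are queen-connected components (the common landscape-metrics
default); the aggregation index counts rook like-adjacencies `g`
against the largest-integer-square maximum `g_max`
(`n = ⌊√A⌋, m = A − n²`; `2n(n−1)` if `m = 0`, `+2m−1` if `m ≤ n`,
`+2m−2` otherwise), AI = 100·g/g_max (0 reported when `g_max = 0`).
CLFI is evaluated over non-overlapping windows (default 20 × 20 cells)
because a single landscape-level value cannot map the geography of
fragmentation. NP and PD are min-max normalized, AREA_MN and AI
inverted (`1 − minmax`) since both fall as fragmentation rises — the
inversion is what makes the composite increase with fragmentation.
Normalization pools the windows of **all** periods jointly so period
means are on one scale; a metric constant across all windows
contributes a neutral 0.5 (with a warning). Period means are taken
over windows containing at least one class cell. The same windowed
metrics of the woodland + grassland mask, rasterized back to cell
resolution, serve as habitat-patch (EHP) covariates for the SDMs.

## Cost surface

The entropy weight method uses min-max standardization over valid
cells (inverted for cost-direction indicators), column shares
`p_ij = x_ij / Σ_i x_ij`, entropies `e_j = −(1/ln n) Σ p ln p` with
`0·ln 0 = 0`, and weights `W_j ∝ 1 − e_j`. Standardization before the
share step is the canonical recipe; it is the one free choice that
moves third-decimal weight values. A spatially constant indicator
carries no information (`e = 1`, weight 0, warning); all-constant
indicator sets are an error. Default indicators: GDP and a per-class
land-use disturbance score (construction 1.0, cropland 0.6, unused
0.3, grassland 0.2, woodland/water 0.1; configurable). The entropy
sample is cells; planning-unit cost is the mean HDI over the unit's
cells.

## Reserve selection

Planning units are grid blocks by default (10 × 10 cells; polygon
units from GeoJSON are supported). Boundary lengths are shared valid
cell edges × cell size; edges facing nodata or the grid border are
outer edges. Units with > 50% reserve coverage are reserved and forced
into every portfolio.

The objective is `Σ cost + BLM · exposed boundary + Σ SPF_f ·
base_f · max(0, (T_f − held_f)/T_f)`. The per-feature base penalty is
a greedy cost-to-meet-target estimate (cheapest units per unit of
feature until the target is met), anchoring the shortfall penalty on
the scale of the cost of fixing it. Targets default to 30% of each
feature's extent (the "30 by 30" framing); SPF defaults to 5 for
species features and 3 for the habitat/carbon features, all
configurable. Exposed boundary counts shared edges with exactly one
side selected plus outer edges of selected units; reserved units count
as selected, so clustering against reserves is not penalized.

Annealing proposes single-unit flips from a random initial portfolio;
the initial temperature is the 90th percentile of |Δ| over 100 random
probes, cooling is geometric to 10⁻³ of the initial temperature over
the iteration budget (default `max(2000, 50·n)`), and each run ends
with greedy descent — single flips, then two-step swaps (one unit in,
one out) — until no improving move remains. Repeated runs (default
100) give the selection frequency; the BLM sweep reports the mean
cost-vs-boundary trade-off and its knee (maximum perpendicular
distance to the chord in the normalized plane). Gaps are available
units with ssoln strictly greater than 0.65.

## Overlay and persistence

The species layer is the union of per-species high-suitability masks
(richness ≥ 1; a stricter richness cutoff is a config option), the
habitat layer the top two quality levels, the carbon layer the top two
of the six zones (configurable). The 2³ truth table yields eight
categories from three-way hotspots to non-significant. Persistent gaps
are the set intersection of per-period gap sets.

## Orchestration and problem sizes

One global seed fans out to per-stage seeds by CRC-32 hashing of stage
names, so adding a stage never perturbs earlier stages' randomness;
re-running a configuration reproduces every artifact bit-for-bit
(SHA-256 digests in the manifest). The default demo scenario —
120 × 120 cells, 3 species, 3 periods, 144 planning units, 100
annealing runs per period — is sized so the full pipeline completes in
about two minutes on one CPU while every stage still has non-trivial
spatial structure to work on.

## Known limitations

* The six-class sensitivity/threat/carbon tables are stand-in
  parameterizations; conclusions about any real region require
  region-calibrated tables.
* Only two member models are built in; richer learners enter via
  external prediction rasters rather than internal refitting, so their
  per-run resplit skill cannot be recomputed internally.
* The Markov land-use generator has no spatial contagion (a
  neighborhood-majority bonus exists but is off by default), so
  simulated change is spatially unstructured relative to real
  urbanization fronts.
* Windowed CLFI uses non-overlapping tiles; a moving-window variant
  would smooth the map but is not implemented.
* Entropy weighting and HDI standardization are cell-based; very
  skewed GDP surfaces can compress the standardized range.
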