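# Methods

`macrorange` re-implements, as a tested pipeline, a global forecasting
analysis for marine macrophytes (canopy-forming brown macroalgae and
seagrasses): build each species' present-day extent of occurrence (EOO)
from point occurrences with an iterative α-hull, model habitat
suitability with presence/pseudo-absence random forests under emissions
scenarios, and derive diversity, habitat-extent, and area-of-occupancy
(AOO) trajectories for 2015–2100. Because the real inputs (hundreds of
thousands of occurrence records; CMIP6-class climate layers; bathymetry
and light fields) are far beyond desk scale, the package ships a
virtual-species world with known ground truth; every stage is validated
by recovering signals planted in that world.

## Spatial model

All fields live on a regular latitude/longitude grid. Cells are half-open
`[lat, lat+res) × [lon, lon+res)` with centers at `lat + res/2`, so point
→ cell assignment is unambiguous; longitudes are confined to [−180, 180)
and antimeridian-crossing grids are rejected. Cell areas use the exact
spherical band formula `A = R² Δλ (sin φ₂ − sin φ₁)` on the authalic
sphere, R = 6371.0 km; all km² outputs inherit this radius. The global
sum of cell areas closes on 4πR² to machine precision, and block-mean
regridding is area-weighted so it conserves the area-weighted global mean
exactly.

Cells with light at the seabed below 50 E m⁻² yr⁻¹ are treated as
uninhabitable for macrophytes and excluded from every habitat product;
the boundary is inclusive (light ≥ 50 is habitable).

## Extent of occurrence (α-hull)

The α-shape of a species' occurrence points is the union of Delaunay
triangles whose circumradius is at most 1/α (Edelsbrunner's
parametrization): α → 0⁺ recovers the convex hull, larger α carves the
hull tighter and can split it into disjoint components — the reason to
prefer it over a convex hull for disjunct (e.g. bipolar) ranges.

α is selected per species by a tightening loop: start at α₀ = 0.001,
increase in steps of 0.005, and at each step compute

    ratio = (relative area reduction vs the previous hull)
          / (records newly lost / total records)

Large ratios mean the hull is shedding empty area cheaply; the loop stops
at the first step where the ratio is defined and falls below 10, and that
step's hull is kept. Numerical conventions: steps that lose no record
leave the ratio undefined and are skipped; a step that would empty the
hull returns the previous hull; boundary points count as contained.
Species whose points admit no 2-D hull (< 3 unique or collinear points)
get the union of their point cells buffered by one cell. Hulls are
rasterized on a grid 10× finer than the analysis grid (a coarse cell is
kept if any fine center falls in the hull), the cells of hull-contained
records are force-included (a record inside the hull is part of the range
by definition, even if rasterization just misses its cell), and the
result is clipped by the light mask. Only species with ≥ 10 records enter
this stage.

## Habitat suitability (random forest)

Presence cells are cells holding ≥ 1 record (per species, and per group
for brown macroalgae / seagrasses / all macrophytes combined).
Pseudo-absences are sampled uniformly without replacement, one per
presence cell, from cells without records: species models draw them from
the light-valid band (giving within-band niche contrast), group models
from the whole ocean (group presences exhaust the narrow band, and the
deep-ocean absences let the forest learn the depth/light limit).

Features are one value per (variable, calendar month): the mean of that
month over the calibration window 2015–2020 — 12 features for each of
sst, air temperature, salinity, productivity and ice cover, plus static
shortwave radiation and depth (62 features). Projection to a year Y
rebuilds the same features from Y's monthly layers, keeping the feature
space identical between calibration and projection. Climatological months
(not 72 separate year-months) are used precisely because projection
requires a stable feature set.

The forest is 500 trees, √p features per split, out-of-bag (OOB) scoring,
fixed seed. Variable elimination starts from the full model and
repeatedly drops the 10 features with the lowest mean impurity decrease
(ties broken by feature name for determinism), refitting until ≤ 10
features remain; the model with the highest OOB accuracy wins, ties going
to the smaller feature set. The fitted object exposes the selection trace,
importances and a `summary()`, and projects probability-of-occurrence
maps p ∈ [0, 1] for any year and scenario.

## Downstream products

* **Diversity**: per-cell species richness is the stacked-SDM estimator
  Σₛ pₛ over the per-species maps clipped to their EOOs. Change between
  years is mapped as `100 · ln(d_Y / d_2015)` (symmetric gains/losses);
  cells below ε = 10⁻⁶ on either side are masked. Trajectories average
  the per-cell change across occupied cells with a cross-cell normal 95%
  CI and are aggregated into 5-year bins [2015–2019], [2020–2024], …
  labeled by bin start. Latitudinal profiles are unweighted row means
  (an area-weighted option exists but is off by default).
* **Habitat extent**: group suitability maps are binarized at p ≥ 0.6 /
  0.7 / 0.8 / 0.9 (inclusive boundary) and the cell areas summed,
  globally and within 12 marine regions supplied as a label raster; the
  percent change is `100 (a_2100 − a_2015)/a_2015` and regional shares
  are percentages of the labeled suitable area (they sum to 100).
* **Area of occupancy**: `AOO_Y = Σ p_Y · area` over the species' EOO
  cells (no dispersal: AOO changes only through p inside the fixed EOO).
  The proportional-expansion alternative is `s_Y · R_2015` with
  `R_2015 = AOO_2015 / s_2015`; the suitable area `s_Y` is
  probability-weighted over all light-valid cells (`Σ p_Y · area`),
  dimensionally consistent with the AOO so that R is a clean occupied
  fraction — a thresholded variant (p ≥ 0.6) is available via
  `suitable_mode="threshold"`. Group trajectories average across species
  (percent change computed per species first, then averaged), with
  cross-species SE.

## The virtual world

The generator emulates the statistical structure of the real inputs, not
their physics: a latitude-graded SST baseline with a hemisphere-phased
seasonal cycle and a linear scenario warming trend (0.20 / 0.35 / 0.50 °C
per decade for the three SSP-like presets); air temperature with a wider
range; salinity and productivity with weak regionally-signed trends;
sea-ice cover confined poleward of an edge that retreats as cover
declines (3 / 5 / 7 percentage points per decade), with noise that never
creates ice where the expected cover is zero; static shortwave radiation
and depth. Two meridional continents define land; depth grows with
distance from the coast (8 m per degree on the shelf), and light at
bottom `PAR₀(φ) e^(−0.08 z)` carves a contiguous coastal band that passes
the 50 E m⁻² yr⁻¹ mask. Per-layer Gaussian noise is seeded by
(seed, variable, year, month), so any layer is reproducible in isolation
and a century of monthly fields never needs to be in memory at once.

Virtual species have product-Gaussian niches over {sst, salinity, light
at bottom, ice cover}; optima are anchored at randomly chosen habitat
cells (so ranges are non-empty), except the ice response, whose optimum
is pinned at zero cover — macrophytes are suppressed under ice, which
plants the polar-expansion signal that ice retreat releases. True
occupancy is deterministic (suitability ≥ 0.4 on light-valid cells) and
computed from noise-free expected fields, so ground truth carries no
observation error; observation error enters only through sampling.
Occurrence records are drawn from occupied cells with effort clustering
(`(1−b) + b·e^(−d/L)` weights toward sampling hotspots, b = 0.5 by
default), 300–800 records per species — mirroring the emulated dataset,
whose record counts greatly exceed species' range-cell counts — with the
point placed uniformly inside the chosen cell.

What the world does **not** emulate: ocean circulation, dispersal,
species interactions, irregular coastlines, spatially correlated noise,
and taxonomic or georeferencing error. Passing recovery tests therefore
demonstrates that the pipeline machinery recovers planted signals under
its own assumptions, not that real-data projections are accurate.

## Ground truth for recovery

The pipeline's central assumption is no dispersal (suitability clipped to
the present-day EOO). Planted-truth comparisons are therefore evaluated
under the same assumption: a species' truth at year Y is its occupancy at
Y intersected with its 2015 occupancy. Without this, species whose true
ranges shift entirely poleward out of their 2015 extent would make the
comparison meaningless (the unrestricted truth counts expansions the
estimator is designed to exclude); the unrestricted range change is
reported alongside for context.

Recovery statistics for diversity and AOO are evaluated on the combined
all-macrophytes group (cross-species means need the pooled sample), while
the polar-expansion direction check uses the brown-macroalgae group
model: the regional habitat analysis is a per-group product, and the
combined group's presence union saturates the narrow shelf band, leaving
its thresholded polar suitability no room to grow even when both real
groups show the planted expansion.

## Problem sizes and configurations

Two standard configurations ship with the package, both on a 2° global
grid with yearly projections 2015–2100:

* the **default** run: 10 species, all three scenarios — used for the
  reproducibility checks and as the `run-all` example;
* the **recovery** run (`recovery_config()`): 20 species under the
  SSP-like-7.0 scenario (the scenario headline projections are usually
  quoted under). Twenty species is the scale at which group-mean
  statistics stabilize on this grid: with 10 species, integer ground-truth
  richness is so granular that the "fraction of localities losing ≥ 10 %"
  statistic cannot be meaningfully matched by a continuous estimator.

The 2° grid (16 200 cells, ~1 100 light-valid) keeps a complete run in
the minutes range; the 0.5° scale of a production analysis is pure
configuration (`resolution_deg=0.5`).

## Known limitations

* Cross-cell confidence intervals ignore spatial autocorrelation.
* Random-forest probabilities drift under the covariate shift of strong
  warming (2100 conditions lie partly outside the training hull), which
  biases stacked-richness change pessimistic relative to binary truth;
  the AOO aggregate, being linear in p, is markedly more robust.
* Pseudo-absences may fall on truly occupied but unsampled cells; at low
  record density this depresses core probabilities.
* The α-hull loop's stopping ratio compares consecutive hulls on the
  planar (degree²) metric, as published; no spherical correction is
  applied at hull scale.
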