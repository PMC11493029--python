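# Methods

## Model overview and assumptions

The analysis treats diffuse pollutant transfer as movement across a cost
surface.  Five factors form the per-cell resistance: relative elevation
(height above the lake level, m), relative slope (angle of descent toward
the lake, °), surface roughness (M = 1/cos ∂, dimensionless, ≥ 1),
fractional vegetation cover ([0, 1]) and land-use class.  Continuous
factors are min–max normalised, oriented so larger always means more
resistance to transfer, and graded into equal-interval scores 1/3/5/7/9;
land use is scored directly (paddy and construction 1, dryland 3, water 5,
grass 7, forest 9 — exporting classes intercept least).  The weighted
overlay uses fixed expert weights 0.20/0.17/0.13/0.24/0.26 (relative
elevation / relative slope / roughness / vegetation / land use); the
weights are taken as given constants, not re-derived.

Minimum cumulative resistance (MCR) from a source mask is the 8-connected
shortest-path cost with link cost `d·(R_a+R_b)/2` — the standard
cost-distance formulation, computed by Dijkstra with a binary heap.  The
outer transform of the cumulative cost is taken as the identity: any
strictly increasing transform leaves the natural-breaks classes and every
correlation *sign* unchanged (Pearson magnitudes would change).  Nodata
cells are impassable.  Risk semantics invert MCR: the five Fisher–Jenks
classes are labelled so the lowest-MCR class is *extremely high risk*.

Two source landscapes are analysed separately throughout: paddy fields
(PFSL) and construction land (CLSL).

## Interpretation choices where the definitions were open

* **Relative slope** is implemented as the lake-relative angle
  `atan(max(0, z − lake_level)/d)` with `d` the Euclidean distance to the
  nearest lake cell (floored at one cell size); a config switch
  (`relative_slope_mode="local"`) substitutes the local Horn slope, the
  likely operational shortcut in GIS practice.  Flow-path distance was
  considered and rejected for determinism and simplicity.
* **Grading** uses value intervals on the normalised range (a quantile
  option exists in config); a constant factor maps to the neutral 0.5 so a
  flat basin cannot dominate through one weight.
* **Lake level** defaults to the minimum DEM elevation over the lake mask.
* **Land-use score table** is configurable; the default encodes the
  interception ordering described above and gives open water the neutral 5.

## Numerical choices

* Dijkstra results are certified in tests by `verify_relaxed`, an
  independent optimality check (zero on sources, no 8-neighbour link can
  relax any label, tolerance 1e-9), and cross-checked against Bellman–Ford
  relaxation oracles.
* Fisher–Jenks uses the exact O(k·n²) dynamic program; ties between
  optimal partitions resolve to the earliest split.  Above a sample cap
  (default 5 000 cells — the quadratic DP makes whole-raster breaks on
  large grids needlessly expensive while a seeded uniform subsample plus
  the global extremes changes breaks negligibly) breaks are computed on a
  subsample and applied to all cells.  Intervals are left-open /
  right-closed except the first.
* D8 ties break in the fixed neighbour order E, SE, S, SW, W, NW, N, NE;
  flats left by priority-flood filling are resolved by breadth-first
  growth from already-draining cells, so routing is deterministic and
  acyclic.  Depression filling accepts an outlet mask: basin-internal
  routing uses the lake cells as outlets so the lake itself is not filled.
* Buffers and the lakeshore band are raster zones by the cell-centre rule
  (a cell belongs if its centre is within the distance), making zonal
  statistics exact set operations; lake cells are excluded from every
  zone, as they carry no landscape resistance.
* Pearson r is clamped to [−1, 1]; |r| within double rounding (1e-12) of 1
  snaps to ±1.  Two-sided p-values use the t-transform on n−2 df.  No
  multiple-testing correction is applied across the up-to-98 correlation
  cells — a deliberate match to per-pair significance starring, and a
  known limitation.

## The synthetic-data generator

`synthetic_basin` emulates a high-plateau lake basin: a radial power-law
bowl (floor 1700 m, rim +400 m) plus smoothed seeded relief damped near
the centre, so one deep lake (default level 1775 m, ~10 % of cells) and
dendritic drainage emerge without hand-drawn inputs.  Defaults are 128×128
cells at 30 m and 19 inflow rivers, matching the sampling structure of the
packaged water-quality table.  Land use is placed by suitability ranking
with seeded spatial noise: construction on flat shoreline cells (8 % of
land), paddy on low-slope cells near rivers (18 %), dryland 12 %, the
remaining slopes splitting into grass and forest; class shares are hit by
count selection.  Vegetation cover is class mean (forest 0.85 … 
construction 0.12) plus Gaussian noise (σ = 0.07), clipped to [0, 1].

Concentrations are planted on the standardized zonal mean MCR z of the
1000 m-buffer PFSL zones:

```
conc = β0 − s·(β1·z + ε),   ε ~ N(0, σ²),   s = β0/3,
```

with β1 = 1 and σ = 0.25 by default and per-index baselines β0 of the
order of real monitoring means (NH3-N 1.4, TP 0.4, …, COD_Cr 21 mg/L).
The per-index amplitude `s` keeps every index on its own concentration
scale while the planted slope and noise stay comparable across indexes;
Pearson correlation is invariant to `s`, so downstream behaviour is
unaffected.  One shared slope per index is used, not per river: the
correlation of interest runs across rivers.  Values are clipped at 0 mg/L
and the clipping rate is reported (kept < 1 % at defaults by the choice of
`s`).  The Gaussian-linear form is this package's own testing device — it
makes calibration measurable, it is not a claim about real water
chemistry.

What passing tests therefore show: the algorithmic stages are exactly
correct (oracle equivalence), and the inference chain recovers a planted
monotone association with calibrated type-I error.  What they do not
show: that real basins satisfy the linear-Gaussian link, that the factor
weights are right, or that 30 m rasters resolve the relevant land-cover
patches — those depend on real data the package does not ship.

## Replication experiment sizes

Calibration runs use 96×96 basins with 19 rivers: the sign-recovery
experiment draws 100 full scenario replicates (terrain, land use, rivers
and noise all reseeded); the null experiment (β1 = 0) fixes one basin
geometry and draws 1 000 effect-free concentration tables, which under
the null is statistically equivalent to redrawing the basin and isolates
the property being measured — the false-positive rate of the correlation
test.  The sizes keep the full suite and the acceptance script each
around a minute on one CPU while leaving the binomial uncertainty of the
measured rates well inside the asserted bands.

## Known limitations

* The MCR surface rests on the identity transform and the stated weight
  set; magnitudes of r are conditional on both.
* Sub-basin delineation is generic D8 with snap-to-maximum-accumulation
  pour points, not a calibrated hydrological model; flat-resolution and
  tie rules, while deterministic, are one of several defensible choices.
* The lakeshore scale has a single zone, so across-river correlation is
  undefined there; rows are emitted flagged `insufficient`.
* No spatial autocorrelation adjustment is made; rivers are treated as
  independent samples.
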