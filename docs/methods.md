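# Methods

## The model

`vegrisk` treats vegetation at a location as the collection of species
recorded there and summarises its climate tolerance by the *typical*
(median) species. For each 100 km × 100 km equal-area cell:

- Safety margins: `S_MAT = median(upper MAT limits) − cell MAT` and
  `S_MAP = cell MAP − median(lower MAP limits)`, where each species'
  limits are the 98th percentile of MAT and 2nd percentile of MAP across
  the climate values matched to its cleaned records. Margins are
  "room to move" quantities: positive when the typical species' limit has
  not yet been reached.
- Exposure: `E_MAT` is the per-cell median across the GCM ensemble of
  (future − current) MAT, aggregated to the coarse grid;
  `E_dry = max(0, −ΔMAP)` — projected wetting contributes no drying
  exposure.
- Risk: `Risk = E − S`, at risk iff `E > S` (strict). Internally both
  variables are positive-when-at-risk; plotting layers negate the MAP
  risk for display so drying deficits point downward.
- Adaptive capacity: median over species present of each species'
  98th−2nd percentile breadth, per variable.

Assumptions worth stating: observed (realized) limits stand in for
fundamental tolerances; presence means "recorded at least once", with no
abundance weighting; the median species summarises a whole assemblage, so
sub-median species may be at risk even where `E < S`; temperature and
precipitation are assessed independently, with no evapotranspiration or
CO₂ interaction.

## Occurrence QC

A record is removed if it meets at least one criterion: unaccepted name,
missing/out-of-region coordinates, upstream outlier flag, cultivated
origin (flag or case-insensitive `cultivat`/`garden` free-text match),
exotic-checklist membership, or non-specimen basis. The audit report
tallies each criterion independently because records frequently meet
several; `retained = input − unique removals` always holds. Duplicates
collapse to the first record in stable input order per
(species, latitude, longitude, month, year, collector) key; strings are
compared after trimming surrounding whitespace with no case folding, and
coordinates at full stored precision — conservative choices that avoid
over-collapsing. Records missing only the date are retained (date is not
an exclusion criterion) and participate in the dedup key as missing.

## Null model

Safety margins in °C and mm are made comparable by standardising each
against 1000 reassignments of observed limits: a draw samples, without
replacement, the cell's observed richness from the pool of species whose
limit is *compatible* with the cell (upper MAT limit ≥ cell MAT; lower
MAP limit ≤ cell MAP), takes the median limit, and forms a null margin;
`z = (observed − null mean)/null sd` with sd on n−1 degrees of freedom.
The compatibility direction was a genuinely open design point: the
alternative ("literal") reading builds nulls exclusively from species
that could *not* tolerate the cell, which forces negative null margins by
construction; it remains available via `pool_constraint="literal"`. If a
pool is smaller than the richness the draw falls back to sampling with
replacement and the cell is flagged; an empty pool or zero null sd leaves
z undefined (flagged, excluded from joint classification). One random
stream per (cell, variable) is derived from the master seed, so
evaluation order and parallelism cannot change results.

## Completeness

Per-cell "abundance" is the count of cleaned, deduplicated records per
species per cell — the only abundance proxy collection data offer. The
bias-corrected Chao1 estimator gives expected richness; cells with
observed/expected < 0.7 are excluded from the risk–capacity regressions
only (boundary 0.7 passes). Maps and per-cell metrics are still computed
for all cells, so spatial products remain continent-wide while the
statistics are restricted to well-sampled cells. The regression itself is
quadratic OLS (two slope terms, df (2, n−3)) — the operationalisation of
a curvilinear fit — with a LOWESS smoother computed for display only.
Reference analyses of this design report the passing-cell count alongside
the regression df without reconciling the two; this package always
reports n next to the df it used.

## Synthetic data

The generator emulates a continental herbarium compilation, not any real
phytogeography. Climate is a linear north–south MAT gradient (default
12–30 °C) and west–east MAP gradient (200–1800 mm) plus a seeded Gaussian
random field (50-km correlation length; sd 0.5 °C / 50 mm) on a 10-km
equal-area grid over an 800 × 800 km extent (64 coarse cells). Each of
120 species occupies the fine cells inside a random disc (radius
80–250 km) whose MAT does not exceed its true upper bound and whose MAP
is not below its true lower bound; bounds are placed at interior
quantiles of the disc's climate (MAT quantile 0.55–0.95, MAP 0.05–0.45)
so each bound genuinely truncates the range and is recoverable from
samples. Collection effort is long-tailed: per-coarse-cell lognormal
multipliers (σ = 1.8, unit mean) on a Poisson expectation of 0.5 records
per occupied fine cell, which yields both complete and incomplete cells
and so exercises the completeness filter. Contamination is injected per
category at configurable rates (defaults 1–5%), each injected record
carrying its category label so QC removals can be audited one-for-one;
duplicates are verbatim copies of distinct valid rows, matching the
dedup key exactly. Pseudo-GCM futures add a mean warming of 2.8 °C and
mean MAP change of −40 mm with symmetric per-model offsets (so the
ensemble median tracks the mean) plus small spatial noise; the
vegetation map is a nearest-seed (Voronoi) mosaic.

What the generator does *not* emulate — taxonomic synonymy, coastal
nodata, spatially correlated contamination, abundance structure, real
dispersal barriers — bounds what passing tests show: they validate the
*machinery* (estimators, bookkeeping, calibration, determinism) under
known truth, not any empirical claim about real floras.

Two special constructions support sharper oracles. The *null scenario*
assigns limits independently of geography and draws each cell's members
uniformly from the climate-compatible pool, making the observed margin
exchangeable with the null draws; the fraction of cells reaching
|z| ≥ 1.96 then has a known ~5% ceiling, which the acceptance script
measures on 500 cells (2500 × 2000 km at 25-km fine resolution, 400
species, richness 15–30 per cell). The *analytic risk scenario*
recomputes each cell's reference margin by brute force from the
generator's own record log and builds warming fields that exceed it by
±1 °C in a chosen cell set, fixing the at-risk classification by
construction.

## Numerical conventions

- Percentiles: linear interpolation of order statistics at
  `h = (n−1)p + 1` — the shared default of the major statistical
  environments; recorded in run metadata because small-sample limits are
  mildly sensitive to the rule. Multiple records in one fine cell retain
  their (identical) climate values: deduplication acts on specimens, not
  values.
- Medians with even counts average the two central values, everywhere.
- Point-in-cell assignment uses half-open intervals [west, east) ×
  [south, north), so boundary points map uniquely; points outside the
  grid or on nodata cells yield missing values and the owning records are
  dropped from limit estimation with a logged count.
- Coarse aggregation is the unweighted mean of contained fine cells with
  data (fine cells are exactly equal-area on synthetic grids); coarse
  cells under a 1% land fraction are excluded.
- Grid I/O uses single-band ESRI ASCII grids with explicit nodata and
  full-precision `repr` floats, so round-trips are exact and outputs
  byte-reproducible. Real-world runs are expected to supply grids already
  in an equal-area projection (e.g. an Albers continental grid);
  reprojection is outside this package's scope.
- Determinism: one master seed fans out to per-module substreams
  (generator order is fixed; the null model derives one stream per
  (cell, variable)); manifests contain no timestamps.

## Problem sizes

Defaults were chosen so a full synthetic study is interactive: the
standard scenario produces ~18k records and fits in a few seconds; the
calibration scenario uses 500 cells × 1000 reassignments (~3 s). Larger
extents, finer grids and more draws scale linearly and are plain config
changes.

## Known limitations

- The at-risk rule is binary and ignores how far `E` exceeds `S` beyond
  the reported `Risk` magnitude.
- Chao1 completeness uses record counts as abundance; collections are
  not abundance samples, so completeness is itself an approximation.
- The quadratic regression is a description of the risk–capacity
  relationship, not a causal model; capacity and margin share inputs
  (the same niche table), which can induce spurious curvature.
- With very small assemblage richness the median limit and the null sd
  are noisy; cells with undefined z are flagged rather than imputed.
- The literal/compatible pool ambiguity in the null model is resolved by
  default to the compatible reading (see above); results under the
  literal reading differ systematically.
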