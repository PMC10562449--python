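# Methods note

## The accounting model

`resalloc` closes, for every grid cell and year, the balance

```
residue_production = burnt + animal_usage + other_usage + left_on_field
```

with all five quantities in Mg/yr on a regular lat/lon grid (0.5° for
full-scale runs; any rectangular extent for tests). Claims on production
are settled in a fixed order — burning, livestock (with trade), other
off-field uses, remainder left on field — because the deficit definition
(burning + livestock demand above 90 % of production) presupposes that
burning is claimed first, and other uses are explicitly limited by what is
then still available. Two hard constraints hold everywhere production is
positive: at least 10 % of residues stay on the field (complete removal is
impractical), and at most 90 % can be removed by all uses combined.

Key modelling assumptions:

* **Residues follow grain.** Gridded residue production is derived from
  grain production via harvest-index-type conversions; a single base-year
  spatial pattern is rescaled so country totals track national annual
  statistics. Sub-national shifts in cropping pattern over time are not
  represented.
* **Livestock demand follows animals.** National meat/milk output is
  spread over cells proportionally to a single head-count snapshot; the
  animal distribution is held fixed across the period while production
  varies. Herd demography is not modelled.
* **Residues are ruminant feed only.** Pigs and poultry get no residue
  feed (residues are unpalatable to monogastrics); poultry gets no residue
  bedding either (industrial poultry bedding is typically sawdust).
* **Burning has first claim, capped.** Fire products count all
  agricultural biomass (locally including e.g. sugar cane); this
  contamination is absorbed solely by the per-cell 90 % cap, with no
  crop-specific fire split.

## Parameters

| Group | Values (defaults) | Units / meaning |
|---|---|---|
| Exponential yield coefficients `a, b` | per crop, e.g. wheat 2.183 / 0.127, maize 2.656 / 0.103 | `a` dimensionless, `b` ha/Mg; `R = aYe^(−bY)` up to `Y = 1/b`, plateau `a/(be)` beyond |
| Linear yield coefficients `c, d` | per crop, e.g. rice 2.56 / 0.22 | `R = Y(c − dY)`, clamped at 0 |
| Constant residue ratios | region × crop table, ~0.9–2.2 | residue mass per grain mass |
| Protein contents | 138 (bovine meat), 137 (sheep/goat meat), 33 (milk) | g protein / kg product |
| FCR | source-specific tables | kg dry-matter feed per kg protein, herd level |
| CRFF | source-specific tables, 0–1 | residue weight fraction of the diet |
| Bedding | cattle 0.375, sheep/goat 0.1, horse 1.5, pig 0.0625 | kg straw/head/day; horses + 420 kg/head/yr chewing |
| Removal cap / min left | 0.90 / 0.10 | fractions of production |
| Trade radius | 20 cells | Chebyshev distance; ≈ 1000 km at the equator for 0.5° cells |
| Other-use bounds | 0.30 poor / 0.10 rich | of production; linear in GDP per capita between $1046 and $12735 (2015 US$) |
| Max return | China 0.60, Europe 0.70, N. America & Oceania 0.80 | cap on left-on-field fraction |
| Straw energy content | 18 MJ/kg | used only in the domestic-fuel cross-check |

The yield coefficients, protein contents, bedding rates and all allocation
constants are the scheme's published values. The regional constant-ratio
table and the three FCR/CRFF source tables are *not* published as part of
the scheme (only their literature sources are named); the packaged YAML
defaults carry representative magnitudes with the right structure and are
meant to be replaced for real-data runs. Correctness tests therefore use
synthetic parameter tables, not the shipped defaults.

## Design choices where the scheme is underdetermined

* **Trade mechanism.** "Favouring local supply" is realised as a strictly
  nearer-ring-first search: deficits draw from exporters at Chebyshev
  distance 1, then 2, … up to 20; within a ring, supply is drawn
  proportionally to exporters' remaining capacity; deficit cells are
  processed in row-major order per radius. No randomness — the allocation
  is a deterministic function of the inputs. Distance is Chebyshev in grid
  cells (a "20-cell" square radius), with longitude wrap-around on global
  grids. An independent brute-force ring enumerator cross-checks the
  implementation on small grids.
* **Where traded residues are booked.** Exports count as `animal_usage` in
  the *exporting* cell — that is where residues physically leave the field
  — which is the only booking consistent with a per-cell sum rule.
* **Linear method clamp.** `Y(c − dY)` goes negative beyond `Y = c/d`;
  residue mass cannot, so the method is clamped at zero there.
* **Yield division guard.** Yields are computed per cell as
  production/area after country rescaling; cells with harvested area below
  10⁻⁶ ha are treated as zero-yield (and hence zero residue for the
  yield-based methods).
* **Bedding and chewing rates are straw as-used.** The per-head rates
  (including the 420 kg/yr horse chewing figure, quoted in fresh matter)
  are applied directly with no fresh-to-dry-matter conversion: the scheme
  states no conversion factor, and applying an undocumented one would be a
  spurious refinement given the uncertainty of the rates themselves.
* **Production-system taxonomy.** The three livestock sources use
  different system classes (urban / industrial / feedlot …); lookups are
  made total by mapping them onto one canonical set {grazing, mixed,
  intensive, other} and falling back region → default and climate → any.
  The mekonnen source has no CRFFs; the herrero CRFF table is substituted
  and the provenance recorded on the parameter object.
* **Dominant system per cell** is the modal fine-grid class, ties broken
  by fixed class order, so coarsening is deterministic.
* **GDP interpolation** is linear in the GDP level (not its logarithm),
  and GDP is re-read every year, so countries move between income bands
  over time.
* **Mean scheme.** The default averages *inputs* per stage (3 production
  methods, the covering fire datasets, 3 livestock sources) and runs the
  allocation once on the means; averaging the 18 finished ledgers instead
  is available as `run_mean(mode="outputs")`. Both yield balanced ledgers.
* **Point-inventory coverage.** The FINN-style fire inventory starts in
  2001 (configurable). Ensemble members using it simply omit earlier
  years, and the mean scheme falls back to the gridded product alone for
  those years: burning is never fabricated for uncovered years.
* **netCDF convention.** Cell centres, latitude ascending
  (−89.75…89.75 / −179.75…179.75 at 0.5°), a `time` dimension holding
  calendar years, five variables with units `Mg/year`; files are written
  through xarray's scipy backend (NETCDF3_CLASSIC). Files refuse to write
  if any cell violates the ledger invariants.
* **Missing data** is NaN in rasters and NaN in tables, never a silent
  zero; ocean cells carry a sentinel country code.

## The synthetic worlds

The generator fabricates all seven input streams from one seeded RNG:
fine-grid (5 arcmin style) per-crop grain and area for a base year;
country tables (grain, area, meat, milk, GDP per capita) as smooth trends
plus noise anchored so base-year country totals equal the gridded sums
exactly; monthly 0.25°-style agricultural burning proportional to a
residue proxy; a point fire inventory mirroring the gridded product plus
non-agricultural records that the class filter must drop; per-species
head-count grids; a categorical system × climate grid; and a country mask
in vertical strips with an ocean corner, covering all three GDP bands and
all four maximum-return classes.

Standard test conditions are a 20×20 window of 0.5° cells, six countries,
years 1997–2021 with base year 2010, yields drawn in 0.5–12 Mg/ha (so both
branches of the exponential formula are exercised), and a fire inventory
from 2001. Three documented configurations exist: `standard_config`
(balanced supply and demand), `deficit_config` (dense-herd hotspots on
suppressed cropland, so a substantial share of cells is in deficit and the
trade stage does real work), and `china_surplus_config` (low burning and
livestock demand, so the maximum-return caps bind).

The generator reproduces the *structure* the scheme relies on — magnitude
contrasts, trends, coverage gaps, regional heterogeneity — not the
statistics of real agriculture. Passing tests therefore demonstrate that
the accounting is correct and its invariants hold under those structural
conditions; they say nothing about the realism of any particular global
magnitude, which depends entirely on the real input datasets.

## Numerical tolerances

* Ledger mass balance and caps: 1e-6 relative per cell.
* Sum-aggregation and country rescaling: conserve totals to 1e-9 relative.
* Exponential-formula continuity at `Y = 1/b`: 1e-12.
* Trade bookkeeping thresholds: 1e-9 Mg (deficits/capacities below this are
  treated as zero).

## Known limitations

* Cereals only; residues of other crops (sugar cane, legumes) enter only
  implicitly through the burning cap. Below-ground residues are excluded.
* No economics: trade ignores prices and transport costs beyond the radius
  limit; other-use demand is a GDP-indexed bound, not a demand model.
* Single livestock snapshot and single base-year crop pattern over the
  whole period.
* The shipped constant-ratio and FCR/CRFF tables are representative
  placeholders, not the cited literature values.
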