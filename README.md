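# resalloc

Gridded accounting of cereal crop-residue production and usage.

Cereal residues — straw and stover — are roughly as much biomass as the
grain itself, and what happens to them matters: residues left on the field
feed soil organic carbon; residues burnt on the field emit CH₄, N₂O and
particulates; residues fed to ruminants underpin a large share of global
meat and milk; and in poorer countries residues are a major domestic fuel.
Yet crop models usually assume a single uniform left-on-field fraction.
`resalloc` implements a complete per-cell accounting scheme that, for every
0.5° grid cell and year, estimates total cereal residue production and
splits it into four uses under a strict mass balance:

```
production = burnt + animal (feed + bedding) + other off-field + left on field
```

It is aimed at agroecosystem and carbon-cycle modellers who need a
spatially explicit residue-management baseline, and it runs end to end on
seeded synthetic inputs, so the whole scheme is testable without any
external downloads.

## The scheme

**Residue production.** Gridded base-year grain production and harvested
area are rescaled each year so country totals match national statistics,
then converted to residues by three alternative methods: fixed regional
residue-to-grain ratios; the saturating exponential residue-yield function

```
R = a·Y·e^(−bY)   for Y ≤ 1/b,      R = a/(b·e)   for Y > 1/b
```

and the linear (parabolic) fit `R = Y·(c − d·Y)` (clamped at zero), where
`Y` is grain yield (Mg/ha) and `a, b, c, d` are crop-specific constants for
barley, maize, rice, wheat, millet, sorghum and other cereals.

**Burning.** Two fire inputs — a monthly 0.25° gridded agricultural-burning
product and a point fire inventory filtered to agricultural fires — are
aggregated to annual 0.5° grids; burnt biomass is capped at 90 % of cereal
residue production per cell.

**Livestock.** National cattle and small-ruminant meat/milk production is
apportioned to cells by head counts, then converted to residue demand via
feed conversion ratios (kg dry-matter feed per kg protein, herd level) and
crop-residue feed fractions, keyed by region, production system and
climate, from three alternative literature sources. Bedding straw is added
at fixed per-head daily rates (plus a chewing allowance for horses).

**Allocation.** Cells whose burning + livestock demand exceeds 90 % of
their own production import surplus from nearby cells (nearest Chebyshev
ring first, up to 20 cells ≈ 1000 km); remaining deficits are treated as
overestimated demand and zeroed. Other off-field uses (domestic fuel,
construction, industry) claim up to 30 % of production in low-income
countries and 10 % in high-income ones, interpolated linearly in GDP per
capita between the World Bank thresholds ($1046 / $12735, 2015 prices).
The remainder is left on the field — always at least 10 %, and at most
60 % in China, 70 % in Europe and 80 % in North America & Oceania (excess
moves to other uses).

Every stage has interchangeable variants (3 production methods × 3
livestock sources × 2 fire datasets), giving an 18-member ensemble plus a
mean scheme; the spread across members is the method uncertainty.

## Worked example

Run the mean scheme on a small synthetic world (10×10 cells, 11 years):

```python
import resalloc as ra

cfg = ra.standard_config(seed=42, nlat=10, nlon=10,
                         year_start=2005, year_end=2015, base_year=2010)
engine = ra.PipelineEngine(ra.make_world(cfg))
L = engine.run_mean()[2010]

print(f"residue production 2010: {L.production.total()*1e-6:.3f} Tg")
for name, f in L.layers().items():
    if name != "residue_production":
        share = 100 * f.total() / L.production.total()
        print(f"  {name:14s}: {f.total()*1e-6:7.3f} Tg  ({share:4.1f} %)")
```

prints

```
residue production 2010: 2.949 Tg
  burnt_residues:   0.274 Tg  ( 9.3 %)
  animal_usage  :   0.354 Tg  (12.0 %)
  other_usage   :   0.707 Tg  (24.0 %)
  left_on_field :   1.614 Tg  (54.7 %)
```

i.e. in this synthetic world about 9 % of the 2.95 Tg of residues are burnt
on the field, 12 % go to livestock feed and bedding, 24 % to other
off-field uses and 55 % stay on the field; the four usage layers sum
exactly to production in every cell. The ensemble spread comes from
`ra.ensemble_range(engine.run_all())`, which tabulates min/mean/max totals
per usage layer across the 18 members.

The same pipeline is exposed on the command line:

```sh
resalloc synth --config world.yaml --out inputs/
resalloc run   --config world.yaml --all --mean --out results/
resalloc summary --config world.yaml --region china
```

`run` writes one netCDF file per member, named
`crop_residue_usage_{constant|exponential|linear}_{herrero|mottet|mekonnen}_{GFED4s|FINN}.nc`,
and `crop_residue_usage_mean.nc` for the mean scheme — five layers
(`residue_production`, `burnt_residues`, `animal_usage`, `other_usage`,
`left_on_field`), units Mg/year, dimensions (time, lat, lon).

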