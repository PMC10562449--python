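"""Crop-residue demand for ruminant feed and animal bedding.

National meat and milk production (cattle and small ruminants) is spread
over the grid in proportion to animal head counts, then converted to
residue demand through feed conversion ratios (FCR, kg dry-matter feed per
kg protein at herd level) and crop-residue feed fractions (CRFF, the weight
fraction of residues in the diet).  FCR and CRFF depend on region, animal
type, production system and climate, and come from one of three literature
sources (``herrero``, ``mottet``, ``mekonnen``).

Bedding straw is a fixed per-head daily rate per species (plus an annual
chewing allowance for horses); monogastric feed plays no role — residues
are unpalatable to pigs and poultry — and poultry bedding is excluded.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np

from .grid import CountryMask, CountrySeries, GridField
from .params import BeddingRates, FeedParams, SYSTEMS, CLIMATES

__all__ = [
    "RUMINANT_PRODUCTS",
    "apportion_production",
    "dominant_system",
    "residue_feed_demand",
    "bedding_demand",
    "animal_usage",
    "encode_system_climate",
    "decode_system_climate",
]

#: (species group, product) pairs carrying residue feed demand, and the
#: head-count grid each one is apportioned by.
RUMINANT_PRODUCTS: tuple[tuple[str, str], ...] = (
    ("cattle", "meat"),
    ("cattle", "milk"),
    ("sheep_goat", "meat"),
    ("sheep_goat", "milk"),
)

DAYS_PER_YEAR = 365.0


# -- production-system grid -------------------------------------------------
#
# The production-system dataset is categorical (system × climate) on a fine
# grid; a combined integer code keeps the two attributes in one raster.

def encode_system_climate(system: str, climate: str) -> int:
    return SYSTEMS.index(system) * len(CLIMATES) + CLIMATES.index(climate)


def decode_system_climate(code: int) -> tuple[str, str]:
    return SYSTEMS[code // len(CLIMATES)], CLIMATES[code % len(CLIMATES)]


def dominant_system(fine: GridField, target_deg: float = 0.5) -> GridField:
    """Modal system×climate class of the fine cells inside each 0.5° cell.

    Ties are broken by the fixed class order of the combined code
    (grazing < mixed < intensive < other, arid < temperate < tropical), so
    the result is deterministic.
    """
    factor_f = target_deg / fine.resolution_deg
    factor = round(factor_f)
    if factor < 1 or abs(factor - factor_f) > 1e-6:
        raise ValueError("fine resolution does not divide the target evenly")
    nlat, nlon = fine.shape
    if nlat % factor or nlon % factor:
        raise ValueError("grid extent is not a whole number of coarse cells")
    codes = fine.values.astype(int)
    blocks = codes.reshape(nlat // factor, factor, nlon // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(nlat // factor, nlon // factor, -1)
    n_classes = len(SYSTEMS) * len(CLIMATES)
    counts = np.stack(
        [(blocks == k).sum(axis=-1) for k in range(n_classes)], axis=-1
    )
    modal = counts.argmax(axis=-1)  # argmax takes the lowest code on ties
    lat0 = fine.lat[0] - fine.resolution_deg / 2
    lon0 = fine.lon[0] - fine.resolution_deg / 2
    return GridField.from_origin(
        modal.astype(float), lat0, lon0, target_deg, year=fine.year,
        units="system_climate_code",
    )


def apportion_production(
    countries: Mapping[int, CountrySeries],
    head_counts: Mapping[str, GridField],
    mask: CountryMask,
    year: int,
) -> dict[tuple[str, str], GridField]:
    """Spread national meat/milk production over cells by head counts.

    Cell value = country production × (cell heads / country heads) for each
    (species group, product).  Countries with production but no mapped
    animals cannot be downscaled and are flagged with a warning.
    """
    out: dict[tuple[str, str], GridField] = {}
    for species, product in RUMINANT_PRODUCTS:
        heads = head_counts[species]
        if not mask.same_grid(heads):
            raise ValueError("head-count grids must share the mask's grid")
        h = np.where(np.isnan(heads.values), 0.0, heads.values)
        grid = np.zeros_like(h)
        var = f"{species}_{product}"
        for code, series in countries.items():
            cells = mask.cells(code)
            if not cells.any():
                continue
            total = series.value(var, year)
            if np.isnan(total):
                continue
            if total < 0:
                raise ValueError(
                    f"negative production {total} for country {code}, {var}, {year}"
                )
            if total == 0:
                continue
            country_heads = h[cells].sum()
            if country_heads <= 0:
                warnings.warn(
                    f"country {code} produces {var} but has no mapped {species}; "
                    "production cannot be gridded",
                    stacklevel=2,
                )
                continue
            grid[cells] = h[cells] * (total / country_heads)
        out[(species, product)] = heads.like(grid, year=year, units="Mg/yr")
    return out


def residue_feed_demand(
    production_grids: Mapping[tuple[str, str], GridField],
    system_grid: GridField,
    params: FeedParams,
    mask: CountryMask,
) -> GridField:
    """Per-cell residue feed demand, Mg dry matter per year.

    For every (species, product): product mass [Mg] × protein content
    [g/kg ≡ kg/Mg] × FCR [kg feed/kg protein] × CRFF, summed over pairs.
    FCR/CRFF are resolved per cell from the country's feed region and the
    cell's production system and climate.
    """
    first = next(iter(production_grids.values()))
    if not mask.same_grid(first) or not first.same_grid(system_grid):
        raise ValueError("production, system grid and mask must align")
    demand = np.zeros_like(first.values)
    codes = system_grid.values.astype(int)
    for code in mask.countries():
        region = mask.region_of(code, "feed", default="default")
        cells = mask.cells(code)
        if not cells.any():
            continue
        for sc_code in np.unique(codes[cells]):
            system, climate = decode_system_climate(int(sc_code))
            sub = cells & (codes == sc_code)
            for (species, product), grid in production_grids.items():
                fcr = params.get_fcr(region, species, system, climate, product)
                crff = params.get_crff(region, species, system, climate, product)
                protein_kg_per_mg = params.protein(species, product)  # g/kg = kg/Mg
                mass = np.where(np.isnan(grid.values), 0.0, grid.values)[sub]
                # kg protein = Mg product × (kg protein / Mg product)
                demand[sub] += mass * protein_kg_per_mg * fcr * crff / 1000.0
    return first.like(demand, units="Mg/yr")


def bedding_demand(
    head_counts: Mapping[str, GridField],
    rates: BeddingRates | None = None,
) -> GridField:
    """Per-cell straw demand for bedding (plus horse chewing), Mg/yr.

    Each species contributes heads × daily rate × 365; horses additionally
    chew 420 kg of straw per head and year.  Species without a configured
    rate (e.g. poultry) contribute nothing.
    """
    rates = rates or BeddingRates()
    first = next(iter(head_counts.values()))
    demand = np.zeros_like(first.values)
    for species, heads in head_counts.items():
        first.require_same_grid(heads)
        h = np.where(np.isnan(heads.values), 0.0, heads.values)
        if (h < 0).any():
            raise ValueError(f"negative head count for {species}")
        kg = h * rates.daily(species) * DAYS_PER_YEAR
        if species == "horse":
            kg = kg + h * rates.horse_chewing_kg_yr
        demand += kg / 1000.0
    return first.like(demand, units="Mg/yr")


def animal_usage(feed: GridField, bedding: GridField) -> GridField:
    """Combined livestock demand (feed + bedding), later trimmed by trade."""
    feed.require_same_grid(bedding)
    f = np.where(np.isnan(feed.values), 0.0, feed.values)
    b = np.where(np.isnan(bedding.values), 0.0, bedding.values)
    return feed.like(f + b, units="Mg/yr")
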