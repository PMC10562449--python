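"""Seeded generator of the seven input datasets the pipeline consumes.

Real runs of the accounting scheme are driven by crop grids, national
statistics tables, two fire products, livestock density grids, a
production-system map and country masks.  This module fabricates all seven
with the statistical structure the scheme assumes, so the full pipeline is
exercisable (and testable) without any downloads:

1. per-crop grain production and harvested area on a fine (5 arcmin style)
   grid for a base year;
2. per-country annual grain/area, meat/milk and GDP-per-capita series;
3. a country mask with the three region lookups (constant-ratio region,
   feed region, maximum-return region);
4. monthly agricultural-burning fields on a half-resolution (0.25° style)
   grid, every year;
5. a point fire inventory with vegetation classes, agricultural and not,
   covering only the later part of the period (as point inventories do);
6. per-species livestock head-count grids (single snapshot);
7. a categorical production-system × climate grid on the fine grid.

Everything is drawn from one seeded generator: the same config and seed
reproduce the bundle bit for bit.  Country totals of the gridded base-year
grain equal the base-year table entries by construction.

The generator aims at the *structure* of the real inputs (magnitude
contrasts, trends, coverage gaps), not at statistical realism of global
agriculture.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .burning import FireRecord
from .grid import OCEAN, CountryMask, CountrySeries, GridField
from .livestock import encode_system_climate
from .params import CLIMATES, CROPS

__all__ = [
    "SyntheticWorldConfig",
    "World",
    "make_world",
    "standard_config",
    "deficit_config",
    "china_surplus_config",
]

GDP_BANDS = ("poor", "middle", "rich")
MAX_RETURN_CLASSES = ("china", "europe", "north_america_oceania", "other")
SPECIES = ("cattle", "sheep_goat", "horse", "pig", "poultry")


@dataclass
class SyntheticWorldConfig:
    """Knobs of the synthetic world.

    The defaults describe the standard test conditions: a 20×20 window of
    0.5° cells, six countries in vertical strips (so every GDP band and
    every maximum-return class is represented), the 1997–2021 year range
    with a 2010 base year, grain yields spanning 0.5–12 Mg/ha so both
    branches of the exponential residue formula are exercised, and a point
    fire inventory that starts in 2001.
    """

    nlat: int = 20
    nlon: int = 20
    lat0: float = 30.0
    lon0: float = 10.0
    resolution_deg: float = 0.5
    fine_factor: int = 6      # crop/system grids at resolution/fine_factor
    burn_factor: int = 2      # burning fields at resolution/burn_factor
    n_countries: int = 6
    year_start: int = 1997
    year_end: int = 2021
    base_year: int = 2010
    seed: int = 0
    # cropping
    yield_range: tuple[float, float] = (0.5, 12.0)
    cropland_fraction: float = 0.7
    crop_presence: float = 0.5
    area_log_mean: float = 3.4    # ln(ha) per fine cell
    area_log_sigma: float = 1.0
    area_max_ha: float = 500.0
    # burning
    burning_intensity: float = 0.08   # fraction of proxy residue production
    fire_record_start_year: int = 2001
    # livestock (heads per 0.5° cell, uniform ranges)
    livestock_density: dict[str, tuple[float, float]] = dfield(
        default_factory=lambda: {
            "cattle": (200.0, 3000.0),
            "sheep_goat": (100.0, 2000.0),
            "horse": (0.0, 50.0),
            "pig": (0.0, 1000.0),
            "poultry": (0.0, 20000.0),
        }
    )
    # Mg product per head and year, uniform ranges per country
    productivity: dict[str, tuple[float, float]] = dfield(
        default_factory=lambda: {
            "cattle_meat": (0.03, 0.07),
            "cattle_milk": (0.5, 1.5),
            "sheep_goat_meat": (0.008, 0.02),
            "sheep_goat_milk": (0.03, 0.12),
        }
    )
    # production-system class frequencies
    system_frequencies: dict[str, float] = dfield(
        default_factory=lambda: {
            "grazing": 0.30, "mixed": 0.50, "intensive": 0.15, "other": 0.05,
        }
    )
    # livestock hotspots (deficit worlds): dense herds on suppressed cropland
    hotspot_fraction: float = 0.0
    hotspot_livestock_multiplier: float = 12.0
    hotspot_crop_suppression: float = 0.08
    ocean_corner_cells: int = 2

    def validate(self) -> "SyntheticWorldConfig":
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid extent must be at least 1x1")
        if self.n_countries < len(MAX_RETURN_CLASSES):
            raise ValueError(
                f"need at least {len(MAX_RETURN_CLASSES)} countries to cover "
                "every maximum-return class and GDP band"
            )
        if self.n_countries > self.nlon:
            raise ValueError("more countries than longitude columns")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if not self.year_start <= self.base_year <= self.year_end:
            raise ValueError("base year outside the year range")
        lo, hi = self.yield_range
        if not 0 < lo < hi:
            raise ValueError("yield range must be positive and increasing")
        return self

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticWorldConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("livestock_density", "productivity"):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        if "yield_range" in raw:
            raw["yield_range"] = tuple(raw["yield_range"])
        return cls(**raw).validate()


@dataclass
class World:
    """The generated input bundle (see module docstring for the seven parts)."""

    config: SyntheticWorldConfig
    grain_fine: dict[str, GridField]        # base-year Mg per fine cell
    area_fine: dict[str, GridField]         # base-year ha per fine cell
    countries: dict[int, CountrySeries]
    mask: CountryMask                       # 0.5° country codes + region maps
    monthly_burning: dict[int, list[GridField]]   # year -> 12 monthly fields
    fire_records: list[FireRecord]
    head_counts: dict[str, GridField]       # heads per 0.5° cell (snapshot)
    system_fine: GridField                  # combined system×climate codes

    @property
    def years(self) -> list[int]:
        return self.config.years

    def fire_record_years(self) -> list[int]:
        """Years the point fire inventory covers."""
        return [y for y in self.years if y >= self.config.fire_record_start_year]


# ---------------------------------------------------------------------------


def _country_strips(cfg: SyntheticWorldConfig) -> np.ndarray:
    """Country code per coarse cell: vertical strips, ocean corner block."""
    codes = np.empty((cfg.nlat, cfg.nlon), dtype=int)
    for j in range(cfg.nlon):
        codes[:, j] = j * cfg.n_countries // cfg.nlon
    k = min(cfg.ocean_corner_cells, cfg.nlat, cfg.nlon)
    if k:
        codes[-k:, :k] = OCEAN
    return codes


def _region_maps(cfg: SyntheticWorldConfig) -> tuple[dict, dict[int, str]]:
    """Region lookups plus the GDP band of each country."""
    bands = {c: GDP_BANDS[c % len(GDP_BANDS)] for c in range(cfg.n_countries)}
    max_return = {
        c: MAX_RETURN_CLASSES[c % len(MAX_RETURN_CLASSES)]
        for c in range(cfg.n_countries)
    }
    constant_ratio = {
        c: ("temperate_industrial" if bands[c] == "rich" else "tropical_smallholder")
        for c in range(cfg.n_countries)
    }
    feed = {c: ("oecd" if bands[c] == "rich" else "non_oecd")
            for c in range(cfg.n_countries)}
    region_maps = {
        "constant_ratio": constant_ratio,
        "feed": feed,
        "max_return": max_return,
    }
    return region_maps, bands


def _annual_multipliers(rng: np.random.Generator, years: list[int],
                        base_year: int, growth_lo: float, growth_hi: float,
                        noise_sd: float) -> np.ndarray:
    """Smooth trend + noise, exactly 1 at the base year."""
    g = rng.uniform(growth_lo, growth_hi)
    yrs = np.asarray(years)
    trend = 1.0 + g * (yrs - base_year)
    noise = rng.normal(0.0, noise_sd, size=len(years))
    noise[yrs == base_year] = 0.0
    return np.maximum(trend * (1.0 + noise), 0.05)


def make_world(config: SyntheticWorldConfig) -> World:
    """Generate the full input bundle from a validated config.

    Deterministic: the same config (including its seed) yields a bit-identical
    bundle.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    years = cfg.years
    f = cfg.fine_factor
    fres = cfg.resolution_deg / f
    nlat_f, nlon_f = cfg.nlat * f, cfg.nlon * f

    # -- mask ------------------------------------------------------------
    codes = _country_strips(cfg)
    region_maps, bands = _region_maps(cfg)
    lat = cfg.lat0 + cfg.resolution_deg / 2 + cfg.resolution_deg * np.arange(cfg.nlat)
    lon = cfg.lon0 + cfg.resolution_deg / 2 + cfg.resolution_deg * np.arange(cfg.nlon)
    mask = CountryMask(codes, lat, lon, cfg.resolution_deg, region_maps)
    land = codes != OCEAN
    codes_fine = np.repeat(np.repeat(codes, f, axis=0), f, axis=1)
    land_fine = codes_fine != OCEAN

    # -- livestock hotspots (deficit worlds) -----------------------------
    hotspot = np.zeros((cfg.nlat, cfg.nlon), dtype=bool)
    if cfg.hotspot_fraction > 0:
        land_idx = np.argwhere(land)
        n_hot = int(round(cfg.hotspot_fraction * len(land_idx)))
        pick = rng.choice(len(land_idx), size=n_hot, replace=False)
        for i, j in land_idx[pick]:
            hotspot[i, j] = True
    hotspot_fine = np.repeat(np.repeat(hotspot, f, axis=0), f, axis=1)

    # -- base-year cropping ----------------------------------------------
    cropland = (rng.random((nlat_f, nlon_f)) < cfg.cropland_fraction) & land_fine
    grain_fine: dict[str, GridField] = {}
    area_fine: dict[str, GridField] = {}
    lo_y, hi_y = cfg.yield_range
    for crop in CROPS:
        present = cropland & (rng.random((nlat_f, nlon_f)) < cfg.crop_presence)
        area = np.where(
            present,
            np.minimum(
                np.exp(rng.normal(cfg.area_log_mean, cfg.area_log_sigma,
                                  (nlat_f, nlon_f))),
                cfg.area_max_ha,
            ),
            0.0,
        )
        area = np.where(hotspot_fine, area * cfg.hotspot_crop_suppression, area)
        yields = rng.uniform(lo_y, hi_y, (nlat_f, nlon_f))
        grain = area * yields
        grain_fine[crop] = GridField.from_origin(
            grain, cfg.lat0, cfg.lon0, fres, year=cfg.base_year, units="Mg/yr"
        )
        area_fine[crop] = GridField.from_origin(
            area, cfg.lat0, cfg.lon0, fres, year=cfg.base_year, units="ha"
        )

    # -- livestock snapshot ----------------------------------------------
    head_counts: dict[str, GridField] = {}
    for species in SPECIES:
        lo, hi = cfg.livestock_density.get(species, (0.0, 0.0))
        heads = rng.uniform(lo, hi, (cfg.nlat, cfg.nlon))
        heads = np.where(hotspot, heads * cfg.hotspot_livestock_multiplier, heads)
        heads = np.where(land, heads, 0.0)
        head_counts[species] = GridField(
            heads, lat.copy(), lon.copy(), cfg.resolution_deg,
            year=cfg.base_year, units="head",
        )

    # -- country tables ---------------------------------------------------
    countries: dict[int, CountrySeries] = {}
    gdp_base_ranges = {
        "poor": (500.0, 950.0),
        "middle": (2000.0, 11000.0),
        "rich": (15000.0, 35000.0),
    }
    for c in range(cfg.n_countries):
        cells_fine = codes_fine == c
        cells = codes == c
        data: dict[str, np.ndarray] = {}
        for crop in CROPS:
            base_p = grain_fine[crop].values[cells_fine].sum()
            base_a = area_fine[crop].values[cells_fine].sum()
            m_p = _annual_multipliers(rng, years, cfg.base_year, -0.01, 0.02, 0.04)
            dm = rng.uniform(-0.004, 0.004)
            m_a = np.maximum(m_p * (1.0 + dm * (np.asarray(years) - cfg.base_year)),
                             0.05)
            m_a[np.asarray(years) == cfg.base_year] = 1.0
            data[f"grain_production_{crop}"] = base_p * m_p
            data[f"harvested_area_{crop}"] = base_a * m_a
        for species in ("cattle", "sheep_goat"):
            total_heads = head_counts[species].values[cells].sum()
            for product in ("meat", "milk"):
                lo, hi = cfg.productivity[f"{species}_{product}"]
                per_head = rng.uniform(lo, hi)
                m = _annual_multipliers(rng, years, cfg.base_year, -0.005, 0.02, 0.05)
                data[f"{species}_{product}"] = total_heads * per_head * m
        lo_g, hi_g = gdp_base_ranges[bands[c]]
        gdp0 = rng.uniform(lo_g, hi_g)
        growth = rng.uniform(-0.005, 0.035)
        yrs = np.asarray(years)
        data["gdp_per_capita"] = gdp0 * (1.0 + growth) ** (yrs - cfg.base_year)
        countries[c] = CountrySeries(c, pd.DataFrame(data, index=years))

    # -- burning -----------------------------------------------------------
    # Proxy residue production per coarse cell drives burning magnitudes.
    proxy = np.zeros((cfg.nlat, cfg.nlon))
    for crop in CROPS:
        blocks = grain_fine[crop].values.reshape(cfg.nlat, f, cfg.nlon, f)
        proxy += 1.3 * blocks.sum(axis=(1, 3))

    bf = cfg.burn_factor
    bres = cfg.resolution_deg / bf
    nlat_b, nlon_b = cfg.nlat * bf, cfg.nlon * bf
    monthly_burning: dict[int, list[GridField]] = {}
    fire_records: list[FireRecord] = []
    for year in years:
        # scale the proxy with each country's grain trend
        scale = np.ones((cfg.nlat, cfg.nlon))
        yi = years.index(year)
        for c in range(cfg.n_countries):
            base = sum(
                countries[c].data[f"grain_production_{crop}"].iloc
                [years.index(cfg.base_year)]
                for crop in CROPS
            )
            now = sum(
                countries[c].data[f"grain_production_{crop}"].iloc[yi]
                for crop in CROPS
            )
            scale[codes == c] = now / base if base > 0 else 1.0
        annual = (
            cfg.burning_intensity * proxy * scale
            * np.exp(rng.normal(0.0, 0.3, proxy.shape))
        )
        annual = np.where(land, annual, 0.0)

        season = rng.dirichlet(np.full(12, 0.7))
        fields = []
        for month in range(12):
            fine_b = np.zeros((nlat_b, nlon_b))
            split = rng.dirichlet(np.ones(bf * bf), size=(cfg.nlat, cfg.nlon))
            for k in range(bf * bf):
                di, dj = divmod(k, bf)
                fine_b[di::bf, dj::bf] = annual * season[month] * split[:, :, k]
            fields.append(
                GridField.from_origin(fine_b, cfg.lat0, cfg.lon0, bres,
                                      year=year, units="Mg/month")
            )
        monthly_burning[year] = fields

        # point inventory: agricultural fires mirroring the gridded product,
        # plus non-agricultural records that the class filter must drop
        if year >= cfg.fire_record_start_year:
            noise = np.exp(rng.normal(0.0, 0.25, annual.shape))
            for i, j in np.argwhere(annual > 0):
                total = annual[i, j] * noise[i, j]
                n_rec = 1 + int(rng.integers(0, 2))
                shares = rng.dirichlet(np.ones(n_rec))
                for s in shares:
                    fire_records.append(FireRecord(
                        lat=float(lat[i] + rng.uniform(-0.24, 0.24)),
                        lon=float(lon[j] + rng.uniform(-0.24, 0.24)),
                        date=date(year, 1, 1)
                        + timedelta(days=int(rng.integers(0, 365))),
                        biomass_burnt=float(total * s),
                        vegetation_class="agricultural",
                    ))
            for _ in range(5):
                i, j = rng.integers(0, cfg.nlat), rng.integers(0, cfg.nlon)
                fire_records.append(FireRecord(
                    lat=float(lat[i] + rng.uniform(-0.24, 0.24)),
                    lon=float(lon[j] + rng.uniform(-0.24, 0.24)),
                    date=date(year, 1, 1)
                    + timedelta(days=int(rng.integers(0, 365))),
                    biomass_burnt=float(rng.uniform(1.0, 50.0)),
                    vegetation_class=str(rng.choice(["forest", "savanna"])),
                ))

    # -- production-system grid -------------------------------------------
    systems = list(cfg.system_frequencies)
    probs = np.array([cfg.system_frequencies[s] for s in systems], dtype=float)
    probs = probs / probs.sum()
    climate_of_country = {
        c: CLIMATES[c % len(CLIMATES)] for c in range(cfg.n_countries)
    }
    sys_draw = rng.choice(len(systems), size=(nlat_f, nlon_f), p=probs)
    sys_codes = np.zeros((nlat_f, nlon_f))
    for c in range(cfg.n_countries):
        clim = climate_of_country[c]
        sel = codes_fine == c
        for k, s in enumerate(systems):
            sys_codes[sel & (sys_draw == k)] = encode_system_climate(s, clim)
    system_fine = GridField.from_origin(
        sys_codes, cfg.lat0, cfg.lon0, fres, units="system_climate_code"
    )

    return World(
        config=cfg,
        grain_fine=grain_fine,
        area_fine=area_fine,
        countries=countries,
        mask=mask,
        monthly_burning=monthly_burning,
        fire_records=fire_records,
        head_counts=head_counts,
        system_fine=system_fine,
    )


# ---------------------------------------------------------------------------
# Documented standard configurations
# ---------------------------------------------------------------------------


def standard_config(seed: int = 0, **overrides) -> SyntheticWorldConfig:
    """The standard test world: balanced supply and demand, light burning."""
    return replace(SyntheticWorldConfig(seed=seed), **overrides).validate()


def deficit_config(seed: int = 0, **overrides) -> SyntheticWorldConfig:
    """A world in which livestock demand outruns local supply.

    Dense-herd hotspots sit on suppressed cropland, so a substantial share
    of cells (well above one in twenty) needs imports or ends up with
    unmet demand — the trade stage does real work here.
    """
    base = SyntheticWorldConfig(
        seed=seed,
        hotspot_fraction=0.30,
        hotspot_livestock_multiplier=12.0,
        hotspot_crop_suppression=0.08,
        burning_intensity=0.15,
        livestock_density={
            "cattle": (500.0, 4000.0),
            "sheep_goat": (200.0, 3000.0),
            "horse": (0.0, 50.0),
            "pig": (0.0, 1000.0),
            "poultry": (0.0, 20000.0),
        },
    )
    return replace(base, **overrides).validate()


def china_surplus_config(seed: int = 0, **overrides) -> SyntheticWorldConfig:
    """A surplus world for exercising the maximum-return caps.

    Burning and livestock demand are kept low, so cells in the China-tagged
    region would be left with nearly all their residues — the 60 % return
    cap must bite.
    """
    base = SyntheticWorldConfig(
        seed=seed,
        burning_intensity=0.02,
        livestock_density={
            "cattle": (10.0, 200.0),
            "sheep_goat": (10.0, 150.0),
            "horse": (0.0, 10.0),
            "pig": (0.0, 200.0),
            "poultry": (0.0, 5000.0),
        },
    )
    return replace(base, **overrides).validate()
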