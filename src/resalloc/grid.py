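"""Shared raster/table types, regridding, masks and netCDF I/O.

Every stage of the residue-accounting pipeline trades in two currencies:

* :class:`GridField` — one value per regular lat/lon cell for one year,
  with declared units.  Global runs use 0.5° cells with centres at
  −89.75…89.75 / −179.75…179.75 (latitude ascending); all operations also
  accept smaller rectangular "toy" extents so the pipeline is testable on
  e.g. a 20×20 window.
* :class:`CountrySeries` — a per-country annual table (grain production and
  harvested area per crop, meat/milk per species group, GDP per capita).

Missing data is NaN in rasters and NaN in tables — never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridField",
    "CountrySeries",
    "CountryMask",
    "UsageLedger",
    "MethodCombo",
    "MEAN_COMBO",
    "LedgerError",
    "OCEAN",
    "USAGE_LAYERS",
    "aggregate_to_half_degree",
    "combo_filename",
    "write_usage_netcdf",
    "read_usage_netcdf",
]

#: Sentinel country code for ocean / no-data cells in a :class:`CountryMask`.
OCEAN: int = -1

#: The five output layers, in mass-balance order (production = sum of rest).
USAGE_LAYERS = (
    "residue_production",
    "burnt_residues",
    "animal_usage",
    "other_usage",
    "left_on_field",
)


class LedgerError(ValueError):
    """A usage ledger violates mass balance or a usage cap."""


# ---------------------------------------------------------------------------
# GridField
# ---------------------------------------------------------------------------


@dataclass
class GridField:
    """A raster of real values on a regular lat/lon grid for one year.

    Parameters
    ----------
    values
        2-D array of shape ``(nlat, nlon)``; NaN marks missing cells.
    lat, lon
        Cell-centre coordinates, ascending, uniformly spaced by
        ``resolution_deg``.
    resolution_deg
        Cell width in degrees.
    year
        Calendar year the field refers to (``None`` for static fields).
    units
        Unit string, e.g. ``"Mg/yr"``.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    resolution_deg: float
    year: int | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridField values must be 2-D (lat, lon)")
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValueError(
                f"shape {self.values.shape} does not match coordinates "
                f"({self.lat.size}, {self.lon.size})"
            )
        if self.lat.size > 1 and not np.all(np.diff(self.lat) > 0):
            raise ValueError("latitude must be ascending")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_origin(
        cls,
        values: np.ndarray,
        lat0: float,
        lon0: float,
        resolution_deg: float,
        year: int | None = None,
        units: str = "",
    ) -> "GridField":
        """Build a field from the south-west corner of its extent."""
        values = np.asarray(values, dtype=float)
        nlat, nlon = values.shape
        r = resolution_deg
        lat = lat0 + r / 2 + r * np.arange(nlat)
        lon = lon0 + r / 2 + r * np.arange(nlon)
        return cls(values, lat, lon, r, year=year, units=units)

    @classmethod
    def zeros_like(cls, other: "GridField", year: int | None = None,
                   units: str | None = None) -> "GridField":
        return cls(
            np.zeros_like(other.values),
            other.lat.copy(),
            other.lon.copy(),
            other.resolution_deg,
            year=other.year if year is None else year,
            units=other.units if units is None else units,
        )

    def like(self, values: np.ndarray, year: int | None = None,
             units: str | None = None) -> "GridField":
        """A new field on this grid with different values."""
        return GridField(
            np.asarray(values, dtype=float),
            self.lat.copy(),
            self.lon.copy(),
            self.resolution_deg,
            year=self.year if year is None else year,
            units=self.units if units is None else units,
        )

    # -- properties --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_global_lon(self) -> bool:
        """True when the grid wraps the full 360° of longitude."""
        return abs(self.lon.size * self.resolution_deg - 360.0) < 1e-6

    def total(self) -> float:
        """Global (NaN-ignoring) sum — the extensive total of the field."""
        return float(np.nansum(self.values))

    def same_grid(self, other: "GridField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def require_same_grid(self, other: "GridField") -> None:
        if not self.same_grid(other):
            raise ValueError("fields are not on the same grid")

    def validate_mass(self) -> None:
        """Assert the field is a valid mass quantity (finite, non-negative)."""
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError(f"negative mass value {finite.min()} in field")
        if np.isinf(self.values).any():
            raise ValueError("infinite value in field")

    def to_dataarray(self, name: str = "field") -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            coords={"lat": self.lat, "lon": self.lon},
            dims=("lat", "lon"),
            name=name,
        )
        da.attrs["units"] = self.units
        da.attrs["resolution_deg"] = self.resolution_deg
        return da


def aggregate_to_half_degree(fine: GridField, target_deg: float = 0.5) -> GridField:
    """Sum-aggregate a fine grid onto a coarser grid whose cells it tiles.

    Intended for extensive quantities (Mg, head counts): each coarse cell is
    the SUM of its constituent fine cells, so the global total is conserved.
    NaN fine cells count as missing (ignored); an all-NaN block yields 0.

    Raises
    ------
    ValueError
        If the fine resolution does not divide ``target_deg`` evenly, or the
        extent is not a whole number of coarse cells.
    """
    factor_f = target_deg / fine.resolution_deg
    factor = round(factor_f)
    if factor < 1 or abs(factor - factor_f) > 1e-6:
        raise ValueError(
            f"resolution {fine.resolution_deg}° does not divide {target_deg}° evenly"
        )
    if factor == 1:
        return fine.like(fine.values.copy())
    nlat, nlon = fine.shape
    if nlat % factor or nlon % factor:
        raise ValueError("grid extent is not a whole number of coarse cells")
    blocks = fine.values.reshape(nlat // factor, factor, nlon // factor, factor)
    coarse = np.nansum(blocks, axis=(1, 3))
    lat0 = fine.lat[0] - fine.resolution_deg / 2
    lon0 = fine.lon[0] - fine.resolution_deg / 2
    return GridField.from_origin(
        coarse, lat0, lon0, target_deg, year=fine.year, units=fine.units
    )


# ---------------------------------------------------------------------------
# Country tables and masks
# ---------------------------------------------------------------------------


@dataclass
class CountrySeries:
    """Annual series of national statistics for one country.

    ``data`` is indexed by calendar year and carries one column per variable
    (``grain_production_<crop>`` in Mg/yr, ``harvested_area_<crop>`` in ha,
    ``<species>_<product>`` in Mg/yr, ``gdp_per_capita`` in 2015 US$).
    Every configured year must be present as a row; missing values are NaN,
    never silently zero.
    """

    country_code: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.is_monotonic_increasing:
            self.data = self.data.sort_index()
        years = self.data.index.to_numpy()
        if years.size and np.any(np.diff(years) != 1):
            raise ValueError(
                f"country {self.country_code}: year index has gaps "
                "(missing years must be explicit NaN rows)"
            )

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.data.index]

    def value(self, variable: str, year: int) -> float:
        """A single annual value; raises KeyError on unknown variable/year."""
        return float(self.data.loc[year, variable])


@dataclass
class CountryMask:
    """Country-code raster plus the country→region lookups the scheme needs.

    ``region_maps`` holds named lookups from country code to region label:

    * ``"constant_ratio"`` — region key of the fixed residue-to-grain ratio
      table (production method 1);
    * ``"feed"`` — region key of the FCR/CRFF tables;
    * ``"max_return"`` — one of ``china`` / ``europe`` /
      ``north_america_oceania`` / ``other``, selecting the cap on the
      fraction of residues left on the field.

    Ocean / no-data cells carry the sentinel code :data:`OCEAN`.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    resolution_deg: float
    region_maps: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def countries(self) -> list[int]:
        codes = np.unique(self.values)
        return [int(c) for c in codes if c != OCEAN]

    def cells(self, code: int) -> np.ndarray:
        """Boolean raster of the cells belonging to one country."""
        return self.values == code

    def region_of(self, code: int, map_name: str, default: str | None = None) -> str:
        mapping = self.region_maps.get(map_name, {})
        if code in mapping:
            return mapping[code]
        if default is not None:
            return default
        raise KeyError(f"country {code} missing from region map {map_name!r}")

    def same_grid(self, f: GridField) -> bool:
        return (
            self.shape == f.shape
            and np.allclose(self.lat, f.lat)
            and np.allclose(self.lon, f.lon)
        )

    def region_cells(self, map_name: str, region: str) -> np.ndarray:
        """Boolean raster of all cells whose country maps to ``region``."""
        out = np.zeros(self.shape, dtype=bool)
        for code in self.countries():
            if self.region_maps.get(map_name, {}).get(code) == region:
                out |= self.values == code
        return out


# ---------------------------------------------------------------------------
# Usage ledger
# ---------------------------------------------------------------------------


@dataclass
class UsageLedger:
    """The five-layer per-cell account of residue production and usage.

    All layers are Mg/yr on the same grid and year and must close the
    per-cell mass balance::

        production = burnt + animal + other + left

    with ``left ≥ 0.10 × production`` and
    ``burnt + animal + other ≤ 0.90 × production`` wherever production is
    positive.
    """

    production: GridField
    burnt: GridField
    animal: GridField
    other: GridField
    left: GridField

    RTOL = 1e-6

    def layers(self) -> dict[str, GridField]:
        return dict(
            zip(
                USAGE_LAYERS,
                (self.production, self.burnt, self.animal, self.other, self.left),
            )
        )

    @property
    def year(self) -> int | None:
        return self.production.year

    def validate(self, min_left_fraction: float = 0.10,
                 removal_cap: float = 0.90) -> None:
        """Raise :class:`LedgerError` (with cell coordinates) on any violation."""
        fields = [self.production, self.burnt, self.animal, self.other, self.left]
        for name, f in zip(USAGE_LAYERS, fields):
            self.production.require_same_grid(f)
            bad = np.isfinite(f.values) & (f.values < -1e-12)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise LedgerError(
                    f"{name} negative at cell (lat={f.lat[i]:.3f}, "
                    f"lon={f.lon[j]:.3f}): {f.values[i, j]}"
                )
        p = self.production.values
        lat, lon = self.production.lat, self.production.lon
        resid = p - (self.burnt.values + self.animal.values
                     + self.other.values + self.left.values)
        scale = np.maximum(np.abs(p), 1.0)
        bad = np.abs(resid) > self.RTOL * scale
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise LedgerError(
                f"mass balance violated at cell (lat={lat[i]:.3f}, "
                f"lon={lon[j]:.3f}): production={p[i, j]}, "
                f"sum of uses={p[i, j] - resid[i, j]}"
            )
        prod_pos = p > 0
        tol = self.RTOL * np.abs(p)
        low_left = prod_pos & (self.left.values < min_left_fraction * p - tol)
        if low_left.any():
            i, j = map(int, np.argwhere(low_left)[0])
            frac = self.left.values[i, j] / p[i, j]
            raise LedgerError(
                f"left-on-field fraction {frac:.4f} < {min_left_fraction} at "
                f"cell (lat={lat[i]:.3f}, lon={lon[j]:.3f})"
            )
        removal = self.burnt.values + self.animal.values + self.other.values
        over = prod_pos & (removal > removal_cap * p + tol)
        if over.any():
            i, j = map(int, np.argwhere(over)[0])
            frac = removal[i, j] / p[i, j]
            raise LedgerError(
                f"removal fraction {frac:.4f} > {removal_cap} at cell "
                f"(lat={lat[i]:.3f}, lon={lon[j]:.3f})"
            )


# ---------------------------------------------------------------------------
# Method combinations and netCDF output
# ---------------------------------------------------------------------------

PRODUCTION_METHODS = ("constant", "exponential", "linear")
LIVESTOCK_SOURCES = ("herrero", "mottet", "mekonnen")
FIRE_DATASETS = ("GFED4s", "FINN")


class MethodCombo(NamedTuple):
    """One of the 18 method combinations (3 production × 3 livestock × 2 fire).

    The ensemble mean scheme is represented by the sentinel
    :data:`MEAN_COMBO` rather than a MethodCombo instance.
    """

    production_method: str
    livestock_source: str
    fire_dataset: str

    def validate(self) -> "MethodCombo":
        if self.production_method not in PRODUCTION_METHODS:
            raise ValueError(f"unknown production method {self.production_method!r}")
        if self.livestock_source not in LIVESTOCK_SOURCES:
            raise ValueError(f"unknown livestock source {self.livestock_source!r}")
        if self.fire_dataset not in FIRE_DATASETS:
            raise ValueError(f"unknown fire dataset {self.fire_dataset!r}")
        return self


#: Sentinel for the mean-of-inputs scheme.
MEAN_COMBO = "mean"


def all_combos() -> list[MethodCombo]:
    """The full 18-member ensemble, in a fixed canonical order."""
    return [
        MethodCombo(p, s, f)
        for p in PRODUCTION_METHODS
        for s in LIVESTOCK_SOURCES
        for f in FIRE_DATASETS
    ]


def combo_filename(combo: MethodCombo | str) -> str:
    """Output filename for a method combination.

    ``crop_residue_usage_{production}_{livestock}_{fire}.nc`` for the 18
    ensemble members, ``crop_residue_usage_mean.nc`` for the mean scheme.
    """
    if combo == MEAN_COMBO:
        return "crop_residue_usage_mean.nc"
    combo = MethodCombo(*combo).validate()
    return (
        f"crop_residue_usage_{combo.production_method}_"
        f"{combo.livestock_source}_{combo.fire_dataset}.nc"
    )


def write_usage_netcdf(
    ledgers: Mapping[int, UsageLedger],
    combo: MethodCombo | str,
    path: str | Path,
    validate: bool = True,
) -> Path:
    """Write a per-year ledger series to one netCDF file.

    ``path`` may be a directory (the conventional filename is appended) or a
    full file path.  Variables are the five usage layers with units
    ``Mg/year`` on dimensions ``(time, lat, lon)``; ``time`` is the calendar
    year.  A ledger that violates mass balance refuses to write.
    """
    if not ledgers:
        raise ValueError("no ledgers to write")
    years = sorted(ledgers)
    first = ledgers[years[0]]
    for y in years:
        led = ledgers[y]
        first.production.require_same_grid(led.production)
        if validate:
            led.validate()

    data = {}
    for name in USAGE_LAYERS:
        stack = np.stack([getattr(ledgers[y], _ATTR_OF[name]).values for y in years])
        data[name] = xr.DataArray(
            stack,
            coords={"time": years, "lat": first.production.lat,
                    "lon": first.production.lon},
            dims=("time", "lat", "lon"),
            attrs={"units": "Mg/year"},
        )
    ds = xr.Dataset(data)
    ds["time"].attrs["units"] = "calendar year"
    ds["lat"].attrs.update(units="degrees_north", long_name="cell centre latitude")
    ds["lon"].attrs.update(units="degrees_east", long_name="cell centre longitude")
    ds.attrs["resolution_deg"] = first.production.resolution_deg
    ds.attrs["grid_registration"] = (
        "cell centres; latitude ascending; global grids run "
        "-89.75..89.75 / -179.75..179.75 at 0.5 deg"
    )
    ds.attrs["combo"] = combo_filename(combo)[len("crop_residue_usage_"):-3]

    path = Path(path)
    if path.is_dir():
        path = path / combo_filename(combo)
    # scipy engine -> NETCDF3_CLASSIC, the only backend guaranteed present
    ds.to_netcdf(path, engine="scipy")
    return path


_ATTR_OF = {
    "residue_production": "production",
    "burnt_residues": "burnt",
    "animal_usage": "animal",
    "other_usage": "other",
    "left_on_field": "left",
}


def read_usage_netcdf(path: str | Path) -> dict[int, UsageLedger]:
    """Read a usage file back into per-year :class:`UsageLedger` objects."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    res = float(ds.attrs.get("resolution_deg",
                             abs(float(ds["lat"][1] - ds["lat"][0]))
                             if ds["lat"].size > 1 else 0.5))
    out: dict[int, UsageLedger] = {}
    for k, t in enumerate(ds["time"].values):
        year = int(t)
        fields = {}
        for name in USAGE_LAYERS:
            fields[_ATTR_OF[name]] = GridField(
                ds[name].values[k],
                ds["lat"].values,
                ds["lon"].values,
                res,
                year=year,
                units="Mg/yr",
            )
        out[year] = UsageLedger(**fields)
    return out
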