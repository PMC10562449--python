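"""On-field burning of agricultural biomass.

Two fire data sources feed the scheme:

* a GFED-style gridded product — monthly agricultural biomass burning on a
  0.25° grid, summed over the year and aggregated to 0.5°;
* a FINN-style point inventory — individual fire records with location,
  date, vegetation class and biomass burnt, of which only agricultural
  fires are binned to the 0.5° grid.

Gridded fire products attribute some burning to non-cereal residues (sugar
cane being the locally dominant case); this is absorbed by capping burnt
biomass in each cell at 90 % of cereal residue production.  The cap runs
before livestock allocation — burning has first claim on the residue mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date

import numpy as np

from .grid import GridField, aggregate_to_half_degree

__all__ = [
    "FireRecord",
    "aggregate_gridded_burning",
    "aggregate_fire_records",
    "cap_burning",
    "mean_burning",
]


@dataclass(frozen=True)
class FireRecord:
    """One fire event from a point-based inventory."""

    lat: float
    lon: float
    date: _date
    biomass_burnt: float  # Mg
    vegetation_class: str  # "agricultural", "forest", "savanna", ...

    def __post_init__(self) -> None:
        if self.biomass_burnt < 0:
            raise ValueError("biomass_burnt must be non-negative")


def aggregate_gridded_burning(monthly: list[GridField]) -> GridField:
    """Annual 0.5° agricultural burning from twelve monthly 0.25° fields.

    Months are summed first, then the 0.25° cells are sum-aggregated into
    the 0.5° cells they tile; both steps conserve the global total.
    """
    if len(monthly) != 12:
        raise ValueError(f"need 12 monthly fields, got {len(monthly)}")
    first = monthly[0]
    annual = np.zeros_like(first.values)
    for m in monthly:
        first.require_same_grid(m)
        annual += np.where(np.isnan(m.values), 0.0, m.values)
    fine = first.like(annual, units="Mg/yr")
    return aggregate_to_half_degree(fine)


def aggregate_fire_records(
    records: list[FireRecord], year: int, template: GridField
) -> GridField:
    """Bin a year's agricultural fire records onto the template's 0.5° grid.

    Non-agricultural vegetation classes (forest, savanna, …) are excluded.
    Records falling outside the template extent are dropped with a warning.
    """
    out = np.zeros_like(template.values)
    r = template.resolution_deg
    lat0 = template.lat[0] - r / 2
    lon0 = template.lon[0] - r / 2
    nlat, nlon = template.shape
    n_dropped = 0
    for rec in records:
        if rec.vegetation_class != "agricultural" or rec.date.year != year:
            continue
        i = int(np.floor((rec.lat - lat0) / r))
        j = int(np.floor((rec.lon - lon0) / r))
        if not (0 <= i < nlat and 0 <= j < nlon):
            n_dropped += 1
            continue
        out[i, j] += rec.biomass_burnt
    if n_dropped:
        warnings.warn(
            f"{n_dropped} fire record(s) outside the grid extent were dropped",
            stacklevel=2,
        )
    return template.like(out, year=year, units="Mg/yr")


def cap_burning(burn: GridField, production: GridField,
                removal_cap: float = 0.90) -> GridField:
    """Limit burnt biomass per cell to ``removal_cap`` of residue production."""
    burn.require_same_grid(production)
    b = np.where(np.isnan(burn.values), 0.0, burn.values)
    p = np.where(np.isnan(production.values), 0.0, production.values)
    return burn.like(np.minimum(b, removal_cap * p), units="Mg/yr")


def mean_burning(datasets: list[GridField]) -> GridField:
    """Cellwise mean across the fire datasets that cover the year.

    The point inventory starts several years after the gridded product; for
    years covered by only one source that source is used alone.  Zero
    available datasets is an error — burning is never fabricated.
    """
    datasets = [d for d in datasets if d is not None]
    if not datasets:
        raise ValueError("no fire dataset covers this year")
    first = datasets[0]
    acc = np.zeros_like(first.values)
    for d in datasets:
        first.require_same_grid(d)
        acc += np.where(np.isnan(d.values), 0.0, d.values)
    return first.like(acc / len(datasets), units="Mg/yr")
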