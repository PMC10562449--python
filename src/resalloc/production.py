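"""Cereal residue production from gridded grain production.

The pipeline carries three alternative estimates of residue production and
their mean:

1. **constant** — fixed region- and crop-specific residue-to-grain ratios
   applied to grain production;
2. **exponential** — residue yield ``R = a Y e^{-bY}`` for grain yield
   ``Y ≤ 1/b``, plateauing at ``a/(b e)`` above (harvest indices decline as
   yields rise, but residue yield saturates rather than falling);
3. **linear** — ``R = Y (c - dY)``, clamped at zero for the (unrealistically
   high) yields where the fitted parabola would go negative.

Grain inputs come as a single base-year gridded snapshot which is rescaled
each year so country totals match the national annual statistics.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np

from .grid import CountryMask, CountrySeries, GridField
from .params import HarvestIndexParams

__all__ = [
    "scale_grain_to_country",
    "residue_yield_exponential",
    "residue_yield_linear",
    "residue_from_ratio",
    "residue_from_yield",
    "total_cereal_residue",
    "mean_production",
]

#: Harvested areas below this (ha) are treated as zero for yield division.
MIN_AREA_HA = 1e-6


def scale_grain_to_country(
    base_grid: GridField,
    base_area: GridField,
    countries: Mapping[int, CountrySeries],
    mask: CountryMask,
    year: int,
    crop: str,
) -> tuple[GridField, GridField]:
    """Rescale a base-year grain snapshot to one year's country totals.

    Each cell keeps its base-year share of the country total; the country
    total is replaced by the national statistic for ``year``.  Harvested
    areas are rescaled by the same rule.  Countries with zero gridded
    base-year production but a nonzero table value cannot be downscaled and
    are flagged with a warning (their cells stay zero).

    Returns ``(production, area)`` fields for the requested year.
    """
    if not mask.same_grid(base_grid) or not mask.same_grid(base_area):
        raise ValueError("base grids must share the country mask's grid")
    prod = np.zeros_like(base_grid.values)
    area = np.zeros_like(base_area.values)
    pvar = f"grain_production_{crop}"
    avar = f"harvested_area_{crop}"
    table_codes = set(countries)
    for code in table_codes:
        cells = mask.cells(code)
        series = countries[code]
        if year not in series.data.index:
            raise KeyError(f"country {code} has no entry for year {year}")
        if not cells.any():
            warnings.warn(
                f"country {code} present in tables but absent from mask; skipped",
                stacklevel=2,
            )
            continue
        for var, base, out in ((pvar, base_grid, prod), (avar, base_area, area)):
            total = series.value(var, year)
            if np.isnan(total):
                continue
            if total < 0:
                raise ValueError(
                    f"negative table value {total} for country {code}, {var}, {year}"
                )
            base_vals = np.where(np.isnan(base.values), 0.0, base.values)
            base_total = base_vals[cells].sum()
            if base_total <= 0:
                if total > 0:
                    warnings.warn(
                        f"country {code} has zero gridded base-year {var} but "
                        f"table total {total}; cannot downscale",
                        stacklevel=2,
                    )
                continue
            out[cells] = base_vals[cells] * (total / base_total)
    return (
        base_grid.like(prod, year=year, units="Mg/yr"),
        base_area.like(area, year=year, units="ha"),
    )


# Cereal classes outside the six named crops resolve to the other_cereals
# row via HarvestIndexParams.abcd; a table with no such row raises KeyError.
def _coeffs(params: HarvestIndexParams, crop: str) -> tuple[float, float, float, float]:
    return params.abcd(crop)


def residue_yield_exponential(
    Y: np.ndarray | float, crop: str, params: HarvestIndexParams | None = None
) -> np.ndarray | float:
    """Residue yield (Mg/ha) from grain yield by the saturating exponential.

    ``R = a Y e^{-bY}`` up to its maximum at ``Y = 1/b``, constant at
    ``a/(b e)`` beyond — continuous at the junction.
    """
    params = params or HarvestIndexParams()
    a, b, _, _ = _coeffs(params, crop)
    Y_arr = np.asarray(Y, dtype=float)
    if np.any(Y_arr < 0):
        raise ValueError("grain yield must be non-negative")
    rising = a * Y_arr * np.exp(-b * Y_arr)
    plateau = a / (b * np.e)
    out = np.where(Y_arr <= 1.0 / b, rising, plateau)
    return float(out) if np.isscalar(Y) else out


def residue_yield_linear(
    Y: np.ndarray | float, crop: str, params: HarvestIndexParams | None = None
) -> np.ndarray | float:
    """Residue yield (Mg/ha) from grain yield by the fitted parabola.

    ``R = Y (c - dY)``, clamped at zero where the fit would go negative
    (yields beyond ``c/d``): residue mass cannot be negative.
    """
    params = params or HarvestIndexParams()
    _, _, c, d = _coeffs(params, crop)
    Y_arr = np.asarray(Y, dtype=float)
    if np.any(Y_arr < 0):
        raise ValueError("grain yield must be non-negative")
    out = np.maximum(0.0, Y_arr * (c - d * Y_arr))
    return float(out) if np.isscalar(Y) else out


def residue_from_ratio(
    production: GridField,
    mask: CountryMask,
    params: HarvestIndexParams,
    crop: str,
) -> GridField:
    """Constant-ratio method: residue = ratio(region, crop) × grain per cell."""
    if not mask.same_grid(production):
        raise ValueError("production field must share the mask's grid")
    out = np.zeros_like(production.values)
    prod = np.where(np.isnan(production.values), 0.0, production.values)
    for code in mask.countries():
        region = mask.region_of(code, "constant_ratio", default="default")
        ratio = params.constant_ratio(region, crop)
        cells = mask.cells(code)
        out[cells] = ratio * prod[cells]
    return production.like(out, units="Mg/yr")


def residue_from_yield(
    production: GridField,
    area: GridField,
    crop: str,
    method: str,
    params: HarvestIndexParams | None = None,
) -> GridField:
    """Yield-based methods applied cell by cell.

    Grain yield is production/area per cell (cells with harvested area below
    ``MIN_AREA_HA`` ha are treated as zero-yield); residue production is the
    residue yield times the harvested area, so zero area implies zero
    residues.
    """
    production.require_same_grid(area)
    prod = np.where(np.isnan(production.values), 0.0, production.values)
    ar = np.where(np.isnan(area.values), 0.0, area.values)
    Y = np.divide(prod, ar, out=np.zeros_like(prod), where=ar >= MIN_AREA_HA)
    if method == "exponential":
        R = residue_yield_exponential(Y, crop, params)
    elif method == "linear":
        R = residue_yield_linear(Y, crop, params)
    else:
        raise ValueError(f"unknown yield method {method!r}")
    return production.like(R * ar, units="Mg/yr")


def total_cereal_residue(per_crop: Mapping[str, GridField]) -> GridField:
    """Cellwise sum of the per-crop residue fields."""
    if not per_crop:
        raise ValueError("no per-crop fields given")
    fields = list(per_crop.values())
    first = fields[0]
    total = np.zeros_like(first.values)
    for f in fields:
        first.require_same_grid(f)
        if f.year != first.year:
            raise ValueError("per-crop fields span different years")
        total += np.where(np.isnan(f.values), 0.0, f.values)
    return first.like(total, units="Mg/yr")


def mean_production(methods: Mapping[str, GridField] | list[GridField]) -> GridField:
    """Cellwise arithmetic mean of the three production-method totals."""
    fields = list(methods.values()) if isinstance(methods, Mapping) else list(methods)
    if len(fields) != 3:
        raise ValueError(f"mean production needs exactly 3 method outputs, got {len(fields)}")
    first = fields[0]
    acc = np.zeros_like(first.values)
    for f in fields:
        first.require_same_grid(f)
        acc += f.values
    return first.like(acc / 3.0, units="Mg/yr")
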