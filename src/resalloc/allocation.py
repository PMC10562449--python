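"""Closing the per-cell residue mass balance.

Claims on each cell's residue production are settled in a fixed order:
burning first (already capped at 90 % of production), then livestock feed
and bedding, then other off-field uses, with the remainder left on the
field.  Three mechanisms keep every cell's account closed:

* **Trade** — cells whose burning + livestock demand exceeds 90 % of their
  own production import surplus from nearby cells, nearest ring first, up
  to a Chebyshev radius of 20 cells (~1000 km at the equator).  Exported
  residues are booked as animal usage in the *exporting* cell — that is
  where they leave the field — which preserves each cell's mass balance.
  Demand that is still unmet after trade is attributed to local
  overestimation of animal usage and zeroed.
* **GDP-dependent other uses** — domestic fuel, construction, industry etc.
  claim up to 30 % of production in low-income countries and 10 % in
  high-income ones, linearly interpolated in GDP per capita between the
  World Bank income thresholds, always limited by what the 90 % removal cap
  leaves available.
* **Maximum return** — in a few regions the fraction left on the field is
  capped (China 60 %, Europe 70 %, North America & Oceania 80 %); excess is
  reassigned to other off-field uses.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .grid import CountryMask, CountrySeries, GridField, UsageLedger
from .params import AllocationParams

__all__ = [
    "trade_residues",
    "gdp_other_use_bound",
    "gdp_bound_grid",
    "assign_other_uses",
    "left_on_field",
    "assemble_ledger",
]

_EPS = 1e-9


def gdp_other_use_bound(
    gdp_per_capita: float | np.ndarray,
    params: AllocationParams | None = None,
) -> float | np.ndarray:
    """Upper bound on the other-off-field-use fraction, from GDP per capita.

    0.30 below the low-income threshold ($1046, 2015 prices), 0.10 above the
    high-income threshold ($12735), linear in GDP per capita between —
    continuous and monotonically non-increasing.
    """
    p = params or AllocationParams()
    gdp = np.asarray(gdp_per_capita, dtype=float)
    if np.any(gdp < 0):
        raise ValueError("GDP per capita must be non-negative")
    t = (gdp - p.gdp_poor_threshold) / (p.gdp_rich_threshold - p.gdp_poor_threshold)
    t = np.clip(t, 0.0, 1.0)
    out = p.other_use_poor + t * (p.other_use_rich - p.other_use_poor)
    return float(out) if np.isscalar(gdp_per_capita) else out


def gdp_bound_grid(
    countries: Mapping[int, CountrySeries],
    mask: CountryMask,
    year: int,
    params: AllocationParams | None = None,
) -> np.ndarray:
    """Rasterize the per-country GDP bound for one year.

    Cells without a country (or without a GDP figure) get the poor-country
    bound — the conservative upper limit; such cells carry no production in
    practice.
    """
    p = params or AllocationParams()
    out = np.full(mask.shape, p.other_use_poor)
    for code, series in countries.items():
        cells = mask.cells(code)
        if not cells.any():
            continue
        try:
            gdp = series.value("gdp_per_capita", year)
        except KeyError:
            continue
        if np.isnan(gdp):
            continue
        out[cells] = gdp_other_use_bound(gdp, p)
    return out


# ---------------------------------------------------------------------------
# Trade
# ---------------------------------------------------------------------------


def _ring_offsets(r: int) -> list[tuple[int, int]]:
    """Cell offsets at exactly Chebyshev distance r, in row-major order."""
    offs = []
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if max(abs(di), abs(dj)) == r:
                offs.append((di, dj))
    return offs


def trade_residues(
    production: GridField,
    burnt: GridField,
    animal_demand: GridField,
    params: AllocationParams | None = None,
) -> tuple[GridField, GridField, pd.DataFrame]:
    """Fill livestock-demand deficits from nearby surplus cells.

    A cell is in deficit when burning plus animal demand exceeds
    ``removal_cap`` (90 %) of its production; its exportable surplus is what
    the cap leaves after its own burning and (current) animal usage.
    Deficits are filled by an expanding Chebyshev-ring search (radius 1…20):
    strictly nearer rings first, and within a ring supply is drawn from
    exporters in proportion to their remaining capacity.  Imports are booked
    as animal usage in the exporting cell.  Deficits still open after the
    search are returned as ``unmet`` and removed from demand.

    Returns ``(animal_usage, unmet_demand, trade_log)`` where the log has
    one row per (importer, exporter) transfer with cell indices and mass.
    """
    p = params or AllocationParams()
    production.require_same_grid(burnt)
    production.require_same_grid(animal_demand)
    prod = np.where(np.isnan(production.values), 0.0, production.values)
    b = np.where(np.isnan(burnt.values), 0.0, burnt.values)
    d = np.where(np.isnan(animal_demand.values), 0.0, animal_demand.values)
    if (d < -1e-12).any():
        raise ValueError("animal demand must be non-negative")
    d = np.maximum(d, 0.0)

    avail = np.maximum(0.0, p.removal_cap * prod - b)  # room under the cap
    local = np.minimum(d, avail)          # demand satisfiable on the spot
    usage = local.copy()                  # booked animal usage per cell
    deficit = d - local
    capacity = avail - usage              # exportable surplus

    nlat, nlon = prod.shape
    wrap = production.is_global_lon
    log_rows: list[tuple[int, int, int, int, float]] = []
    deficit_cells = [tuple(ix) for ix in np.argwhere(deficit > _EPS)]

    for r in range(1, p.trade_radius_cells + 1):
        if not deficit_cells:
            break
        offsets = _ring_offsets(r)
        still_open = []
        for (i, j) in deficit_cells:
            need = deficit[i, j]
            if need <= _EPS:
                continue
            ring = []
            caps = []
            for di, dj in offsets:
                ii = i + di
                if not 0 <= ii < nlat:
                    continue
                jj = j + dj
                if wrap:
                    jj %= nlon
                elif not 0 <= jj < nlon:
                    continue
                c = capacity[ii, jj]
                if c > _EPS:
                    ring.append((ii, jj))
                    caps.append(c)
            if ring:
                total = float(np.sum(caps))
                take = min(need, total)
                for (ii, jj), c in zip(ring, caps):
                    amount = take * c / total
                    if amount <= 0:
                        continue
                    capacity[ii, jj] -= amount
                    usage[ii, jj] += amount
                    log_rows.append((ii, jj, i, j, amount))
                deficit[i, j] = need - take
            if deficit[i, j] > _EPS:
                still_open.append((i, j))
        deficit_cells = still_open

    unmet = np.where(deficit > _EPS, deficit, 0.0)
    log = pd.DataFrame(
        log_rows, columns=["from_i", "from_j", "to_i", "to_j", "mass_mg"]
    )
    return (
        production.like(usage, units="Mg/yr"),
        production.like(unmet, units="Mg/yr"),
        log,
    )


# ---------------------------------------------------------------------------
# Other uses and left on field
# ---------------------------------------------------------------------------


def assign_other_uses(
    production: GridField,
    burnt: GridField,
    animal: GridField,
    gdp_bound: np.ndarray,
    params: AllocationParams | None = None,
) -> GridField:
    """Other off-field uses: GDP bound × production, limited by availability.

    ``other = min(bound × production, removal_cap × production − burnt −
    animal)``, floored at zero.  Requires the post-trade state, where
    burning + animal usage already respect the cap.
    """
    p = params or AllocationParams()
    production.require_same_grid(burnt)
    production.require_same_grid(animal)
    prod = np.where(np.isnan(production.values), 0.0, production.values)
    b = np.where(np.isnan(burnt.values), 0.0, burnt.values)
    a = np.where(np.isnan(animal.values), 0.0, animal.values)
    room = p.removal_cap * prod - b - a
    if (room < -1e-6 * np.maximum(prod, 1.0)).any():
        raise ValueError(
            "burning + animal usage exceed the removal cap; run trade first"
        )
    other = np.minimum(gdp_bound * prod, np.maximum(room, 0.0))
    return production.like(np.maximum(other, 0.0), units="Mg/yr")


def left_on_field(
    production: GridField,
    burnt: GridField,
    animal: GridField,
    other: GridField,
    mask: CountryMask,
    params: AllocationParams | None = None,
) -> tuple[GridField, GridField]:
    """Residual layer, with regional maximum-return caps applied.

    ``left = production − burnt − animal − other``; in regions with a
    maximum return fraction m (China 0.60, Europe 0.70, North America &
    Oceania 0.80) any excess of left over m × production is moved to other
    off-field uses.  Returns ``(left, other_adjusted)``.
    """
    p = params or AllocationParams()
    prod = np.where(np.isnan(production.values), 0.0, production.values)
    b = np.where(np.isnan(burnt.values), 0.0, burnt.values)
    a = np.where(np.isnan(animal.values), 0.0, animal.values)
    o = np.where(np.isnan(other.values), 0.0, other.values).copy()
    left = prod - b - a - o
    if (left < -1e-6 * np.maximum(prod, 1.0)).any():
        i, j = map(int, np.argwhere(left < -1e-6 * np.maximum(prod, 1.0))[0])
        raise ValueError(
            f"negative left-on-field at cell ({i}, {j}): upstream cap violated"
        )
    left = np.maximum(left, 0.0)
    for region, m in p.max_return.items():
        cells = mask.region_cells("max_return", region)
        if not cells.any():
            continue
        limit = m * prod
        excess = np.where(cells, np.maximum(left - limit, 0.0), 0.0)
        left -= excess
        o += excess
    return (
        production.like(left, units="Mg/yr"),
        production.like(o, units="Mg/yr"),
    )


def assemble_ledger(
    production: GridField,
    burnt: GridField,
    animal: GridField,
    other: GridField,
    left: GridField,
    params: AllocationParams | None = None,
) -> UsageLedger:
    """Build and validate the five-layer ledger; raises on any violation."""
    p = params or AllocationParams()
    ledger = UsageLedger(production, burnt, animal, other, left)
    ledger.validate(min_left_fraction=p.min_left_fraction,
                    removal_cap=p.removal_cap)
    return ledger
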