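"""Orchestration of the 18 method combinations and the mean scheme.

The accounting scheme has three interchangeable stages — residue production
(constant / exponential / linear), fire dataset (gridded GFED4s-style /
point FINN-style) and livestock source (herrero / mottet / mekonnen) —
giving 3 × 3 × 2 = 18 independent calculations, plus a mean scheme that
averages each stage's variants *before* allocation and runs the single
trade → other-uses → left-on-field closure once on the means.

Stage outputs depend only on their own method choice, so the engine caches
them: running all 18 combos costs 3 production series + 2 burning series +
3 demand series + 18 allocations, not 18 full pipelines.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from . import allocation as alloc_mod
from . import burning as burn_mod
from . import livestock as live_mod
from . import production as prod_mod
from .grid import (
    CountryMask,
    GridField,
    MethodCombo,
    UsageLedger,
    aggregate_to_half_degree,
    all_combos,
)
from .params import (
    AllocationParams,
    BeddingRates,
    HarvestIndexParams,
    load_feed_params,
)
from .synth import World

__all__ = [
    "PipelineEngine",
    "run_combo",
    "run_mean",
    "run_all",
    "ensemble_range",
]

log = logging.getLogger(__name__)


class PipelineEngine:
    """Caches stage outputs of one world so ensemble runs share work."""

    def __init__(
        self,
        world: World,
        harvest_params: HarvestIndexParams | None = None,
        feed_params: Mapping[str, object] | None = None,
        bedding_rates: BeddingRates | None = None,
        alloc_params: AllocationParams | None = None,
    ) -> None:
        self.world = world
        self.hi = harvest_params or HarvestIndexParams()
        self.feed = feed_params or {
            s: load_feed_params(s) for s in ("herrero", "mottet", "mekonnen")
        }
        self.bedding = bedding_rates or BeddingRates()
        self.alloc = alloc_params or AllocationParams()
        self.mask: CountryMask = world.mask

        self.base_grain = {
            crop: aggregate_to_half_degree(f) for crop, f in world.grain_fine.items()
        }
        self.base_area = {
            crop: aggregate_to_half_degree(f) for crop, f in world.area_fine.items()
        }
        self.system = live_mod.dominant_system(world.system_fine)
        self._template = next(iter(self.base_grain.values()))
        self._bedding_grid = live_mod.bedding_demand(
            world.head_counts, self.bedding
        )
        self._scaled: dict[int, dict[str, tuple[GridField, GridField]]] = {}
        self._production: dict[tuple[str, int], GridField] = {}
        self._burn_raw: dict[tuple[str, int], GridField | None] = {}
        self._demand: dict[tuple[str, int], GridField] = {}

    # -- stage caches ------------------------------------------------------

    def scaled_grain(self, year: int) -> dict[str, tuple[GridField, GridField]]:
        if year not in self._scaled:
            self._scaled[year] = {
                crop: prod_mod.scale_grain_to_country(
                    self.base_grain[crop], self.base_area[crop],
                    self.world.countries, self.mask, year, crop,
                )
                for crop in self.base_grain
            }
        return self._scaled[year]

    def production_total(self, method: str, year: int) -> GridField:
        key = (method, year)
        if key not in self._production:
            per_crop: dict[str, GridField] = {}
            for crop, (prod, area) in self.scaled_grain(year).items():
                if method == "constant":
                    per_crop[crop] = prod_mod.residue_from_ratio(
                        prod, self.mask, self.hi, crop
                    )
                else:
                    per_crop[crop] = prod_mod.residue_from_yield(
                        prod, area, crop, method, self.hi
                    )
            self._production[key] = prod_mod.total_cereal_residue(per_crop)
        return self._production[key]

    def mean_production(self, year: int) -> GridField:
        return prod_mod.mean_production(
            [self.production_total(m, year) for m in ("constant", "exponential",
                                                      "linear")]
        )

    def raw_burning(self, dataset: str, year: int) -> GridField | None:
        """Uncapped annual agricultural burning; None if the dataset does
        not cover the year (the point inventory starts late)."""
        key = (dataset, year)
        if key not in self._burn_raw:
            if dataset == "GFED4s":
                field = burn_mod.aggregate_gridded_burning(
                    self.world.monthly_burning[year]
                )
            elif dataset == "FINN":
                if year in self.world.fire_record_years():
                    field = burn_mod.aggregate_fire_records(
                        self.world.fire_records, year, self._template
                    )
                else:
                    field = None
            else:
                raise ValueError(f"unknown fire dataset {dataset!r}")
            self._burn_raw[key] = field
        return self._burn_raw[key]

    def mean_raw_burning(self, year: int) -> GridField:
        return burn_mod.mean_burning(
            [self.raw_burning(d, year) for d in ("GFED4s", "FINN")]
        )

    def animal_demand(self, source: str, year: int) -> GridField:
        key = (source, year)
        if key not in self._demand:
            apportioned = live_mod.apportion_production(
                self.world.countries, self.world.head_counts, self.mask, year
            )
            feed = live_mod.residue_feed_demand(
                apportioned, self.system, self.feed[source], self.mask
            )
            self._demand[key] = live_mod.animal_usage(feed, self._bedding_grid)
        return self._demand[key]

    def mean_animal_demand(self, year: int) -> GridField:
        grids = [self.animal_demand(s, year)
                 for s in ("herrero", "mottet", "mekonnen")]
        acc = sum(g.values for g in grids) / len(grids)
        return grids[0].like(acc)

    # -- allocation --------------------------------------------------------

    def allocate(self, production: GridField, raw_burn: GridField,
                 demand: GridField, year: int) -> UsageLedger:
        burnt = burn_mod.cap_burning(raw_burn, production,
                                     self.alloc.removal_cap)
        animal, unmet, trade_log = alloc_mod.trade_residues(
            production, burnt, demand, self.alloc
        )
        bound = alloc_mod.gdp_bound_grid(self.world.countries, self.mask,
                                         year, self.alloc)
        other = alloc_mod.assign_other_uses(production, burnt, animal, bound,
                                            self.alloc)
        left, other = alloc_mod.left_on_field(production, burnt, animal,
                                              other, self.mask, self.alloc)
        ledger = alloc_mod.assemble_ledger(production, burnt, animal, other,
                                           left, self.alloc)
        log.info(
            "year %d: production %.3e, burnt %.3e, animal %.3e (traded %.3e, "
            "unmet-zeroed %.3e), other %.3e, left %.3e [Mg]",
            year, production.total(), burnt.total(), animal.total(),
            trade_log["mass_mg"].sum() if len(trade_log) else 0.0,
            unmet.total(), other.total(), left.total(),
        )
        return ledger

    def run_combo(self, combo: MethodCombo) -> dict[int, UsageLedger]:
        combo = MethodCombo(*combo).validate()
        out: dict[int, UsageLedger] = {}
        for year in self.world.years:
            raw = self.raw_burning(combo.fire_dataset, year)
            if raw is None:
                continue  # documented skip: never fabricate burning
            production = self.production_total(combo.production_method, year)
            demand = self.animal_demand(combo.livestock_source, year)
            out[year] = self.allocate(production, raw, demand, year)
        return out

    def run_mean(self, mode: str = "inputs") -> dict[int, UsageLedger]:
        """The mean scheme.

        ``mode="inputs"`` (default) averages each stage's variants first —
        production over the 3 methods, burning over the covering fire
        datasets, demand over the 3 livestock sources — and runs the single
        allocation (trade → other uses → left) once on the means.
        ``mode="outputs"`` instead averages the 18 finished ledgers cellwise
        (per year, over the members that cover it); the mean of balanced
        ledgers is itself balanced, since every ledger constraint is linear.
        """
        if mode == "outputs":
            return self._mean_of_outputs()
        if mode != "inputs":
            raise ValueError(f"unknown mean mode {mode!r}")
        out: dict[int, UsageLedger] = {}
        for year in self.world.years:
            production = self.mean_production(year)
            raw = self.mean_raw_burning(year)
            demand = self.mean_animal_demand(year)
            out[year] = self.allocate(production, raw, demand, year)
        return out

    def _mean_of_outputs(self) -> dict[int, UsageLedger]:
        per_combo = self.run_all()
        out: dict[int, UsageLedger] = {}
        for year in self.world.years:
            members = [l[year] for l in per_combo.values() if year in l]
            fields = {}
            for attr in ("production", "burnt", "animal", "other", "left"):
                acc = sum(getattr(m, attr).values for m in members)
                fields[attr] = members[0].production.like(
                    acc / len(members), year=year
                )
            out[year] = UsageLedger(**fields)
        return out

    def run_all(self) -> dict[MethodCombo, dict[int, UsageLedger]]:
        return {combo: self.run_combo(combo) for combo in all_combos()}


# -- thin functional surface ------------------------------------------------


def run_combo(world: World, combo: MethodCombo | tuple[str, str, str],
              **engine_kwargs) -> dict[int, UsageLedger]:
    """Run the full pipeline for one method combination."""
    return PipelineEngine(world, **engine_kwargs).run_combo(MethodCombo(*combo))


def run_mean(world: World, **engine_kwargs) -> dict[int, UsageLedger]:
    """Run the mean-of-inputs scheme (the default dataset)."""
    return PipelineEngine(world, **engine_kwargs).run_mean()


def run_all(world: World, **engine_kwargs) -> dict[MethodCombo, dict[int, UsageLedger]]:
    """Run all 18 combinations, sharing stage computations."""
    return PipelineEngine(world, **engine_kwargs).run_all()


def ensemble_range(
    ledgers_by_combo: Mapping[object, Mapping[int, UsageLedger]],
    region_cells: np.ndarray | None = None,
) -> pd.DataFrame:
    """Min/mean/max of regional usage totals across ensemble members.

    Totals are summed over the region (all cells when ``region_cells`` is
    None) and over the years covered by *every* member, so members with
    shorter fire-dataset coverage are compared on common ground.

    Returns a DataFrame indexed by usage layer with columns min/mean/max.
    """
    if not ledgers_by_combo:
        raise ValueError("ensemble range needs at least one member")
    year_sets = [set(l) for l in ledgers_by_combo.values()]
    years = sorted(set.intersection(*year_sets))
    if not years:
        raise ValueError("ensemble members share no years")
    rows = {}
    for name, ledgers in ledgers_by_combo.items():
        totals = {}
        for layer_name in ("residue_production", "burnt_residues",
                           "animal_usage", "other_usage", "left_on_field"):
            s = 0.0
            for y in years:
                field = ledgers[y].layers()[layer_name]
                v = np.where(np.isnan(field.values), 0.0, field.values)
                if region_cells is not None:
                    if not region_cells.any():
                        raise ValueError("empty aggregation region")
                    v = v[region_cells]
                s += float(v.sum())
            totals[layer_name] = s
        rows[name] = totals
    df = pd.DataFrame(rows).T
    return pd.DataFrame(
        {"min": df.min(axis=0), "mean": df.mean(axis=0), "max": df.max(axis=0)}
    )
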