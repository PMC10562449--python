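"""Scheme constants: harvest-index parameters, feed tables, caps and thresholds.

Three groups of parameters drive the accounting scheme:

* :class:`HarvestIndexParams` — per-crop coefficients of the two empirical
  yield-to-residue-yield functions (exponential ``R = aY e^{-bY}`` with a
  plateau, and linear ``R = Y(c - dY)``), plus region-specific constant
  residue-to-grain ratios for the fixed-ratio method.
* :class:`FeedParams` / :class:`BeddingRates` — livestock-side conversion
  factors (feed conversion ratios, crop-residue feed fractions, protein
  contents, per-head bedding straw).
* :class:`AllocationParams` — the caps and thresholds that close the per-cell
  mass balance (90 % removal cap, 10 % minimum left on field, 20-cell trade
  radius, GDP-dependent other-use bounds, regional maximum return fractions).

Everything is overridable from YAML; the defaults shipped here are the
scheme's published constants where those are printed, and documented
representative values where only the literature source is named (the
regional constant ratios and the three FCR/CRFF tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "CROPS",
    "HarvestIndexParams",
    "FeedParams",
    "BeddingRates",
    "AllocationParams",
    "load_feed_params",
    "china_domestic_fuel_share",
    "trade_radius_km",
    "KM_PER_DEGREE",
]

#: The seven cereal classes carried through the pipeline.
CROPS = ("barley", "maize", "rice", "wheat", "millet", "sorghum", "other_cereals")

# Exponential (a, b) and linear (c, d) coefficients per crop.
# a, c dimensionless; b, d in ha/Mg.
_YIELD_COEFFS: dict[str, tuple[float, float, float, float]] = {
    "barley": (1.822, 0.149, 2.77, 0.27),
    "maize": (2.656, 0.103, 2.2, 0.13),
    "rice": (2.45, 0.084, 2.56, 0.22),
    "wheat": (2.183, 0.127, 1.96, 0.14),
    "millet": (1.9, 0.250, 4.38, 0.95),
    "sorghum": (2.302, 0.100, 4.55, 0.55),
    "other_cereals": (1.9, 0.250, 2.7, 0.2),
}

# Representative region-specific residue-to-grain ratios for the
# fixed-ratio production method.  The scheme sources these from the feed
# literature; they are not part of the printed constants, so this default
# table carries typical straw:grain magnitudes and is meant to be replaced
# from YAML for real-data runs.
_DEFAULT_CONSTANT_RATIOS: dict[str, dict[str, float]] = {
    "default": {
        "barley": 1.2,
        "maize": 1.0,
        "rice": 1.4,
        "wheat": 1.3,
        "millet": 1.8,
        "sorghum": 1.8,
        "other_cereals": 1.3,
    },
    "temperate_industrial": {
        "barley": 1.1,
        "maize": 0.9,
        "rice": 1.3,
        "wheat": 1.1,
        "millet": 1.6,
        "sorghum": 1.6,
        "other_cereals": 1.2,
    },
    "tropical_smallholder": {
        "barley": 1.4,
        "maize": 1.3,
        "rice": 1.6,
        "wheat": 1.5,
        "millet": 2.2,
        "sorghum": 2.2,
        "other_cereals": 1.5,
    },
}


@dataclass
class HarvestIndexParams:
    """Grain-to-residue conversion coefficients.

    ``coeffs[crop] = (a, b, c, d)`` with a, b for the exponential method and
    c, d for the linear method.  ``constant_ratios[region][crop]`` is the
    fixed residue-to-grain ratio of the constant method.  Crops outside the
    six named cereals fall back to the ``other_cereals`` row.
    """

    coeffs: dict[str, tuple[float, float, float, float]] = dfield(
        default_factory=lambda: dict(_YIELD_COEFFS)
    )
    constant_ratios: dict[str, dict[str, float]] = dfield(
        default_factory=lambda: {r: dict(c) for r, c in _DEFAULT_CONSTANT_RATIOS.items()}
    )

    def __post_init__(self) -> None:
        for crop, (a, b, c, d) in self.coeffs.items():
            if min(a, b, c, d) <= 0:
                raise ValueError(f"coefficients for {crop} must be positive")

    def abcd(self, crop: str) -> tuple[float, float, float, float]:
        if crop in self.coeffs:
            return self.coeffs[crop]
        if "other_cereals" in self.coeffs:
            return self.coeffs["other_cereals"]
        raise KeyError(f"unknown crop {crop!r} and no other_cereals fallback")

    def constant_ratio(self, region: str, crop: str) -> float:
        table = self.constant_ratios.get(region)
        if table is None:
            table = self.constant_ratios.get("default")
        if table is None:
            raise KeyError(
                f"no constant residue ratio for region {region!r}, crop {crop!r}"
            )
        key = crop if crop in table else "other_cereals"
        if key not in table:
            raise KeyError(
                f"no constant residue ratio for region {region!r}, crop {crop!r}"
            )
        return table[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HarvestIndexParams":
        raw = yaml.safe_load(Path(path).read_text())
        coeffs = {c: tuple(v) for c, v in raw.get("coeffs", _YIELD_COEFFS).items()}
        ratios = raw.get("constant_ratios", _DEFAULT_CONSTANT_RATIOS)
        return cls(coeffs=coeffs, constant_ratios=ratios)


# ---------------------------------------------------------------------------
# Livestock feed parameters
# ---------------------------------------------------------------------------

#: g protein per kg product.
PROTEIN_CONTENT = {
    "cattle_meat": 138.0,
    "sheep_goat_meat": 137.0,
    "milk": 33.0,
}

#: Canonical production-system classes used for FCR/CRFF lookups.
SYSTEMS = ("grazing", "mixed", "intensive", "other")
CLIMATES = ("arid", "temperate", "tropical")

# The three source taxonomies differ; this mapping makes lookups total.
SYSTEM_ALIASES = {
    "urban": "intensive",
    "industrial": "intensive",
    "feedlot": "intensive",
}


@dataclass
class FeedParams:
    """FCR/CRFF tables from one literature source.

    ``fcr[(region, animal, system, climate, product)]`` is kg dry-matter feed
    per kg protein at herd level; ``crff`` (same key) is the fraction by
    weight of crop residues in the diet.  Lookups fall back region →
    ``default`` region, climate → ``any``, so that every query resolves.

    The ``mekonnen`` source publishes FCRs only; its CRFFs are taken from the
    ``herrero`` table (recorded in :attr:`crff_provenance`).
    """

    source: str
    fcr: dict[tuple[str, str, str, str, str], float]
    crff: dict[tuple[str, str, str, str, str], float]
    protein_content: dict[str, float] = dfield(
        default_factory=lambda: dict(PROTEIN_CONTENT)
    )
    crff_provenance: str = ""

    def __post_init__(self) -> None:
        if not self.crff_provenance:
            self.crff_provenance = self.source
        for k, v in self.fcr.items():
            if v <= 0:
                raise ValueError(f"FCR must be positive, got {v} at {k}")
        for k, v in self.crff.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CRFF must lie in [0, 1], got {v} at {k}")

    def _lookup(self, table: Mapping[tuple[str, str, str, str, str], float],
                region: str, animal: str, system: str, climate: str,
                product: str) -> float:
        system = SYSTEM_ALIASES.get(system, system)
        for r in (region, "default"):
            for c in (climate, "any"):
                for s in (system, "any"):
                    key = (r, animal, s, c, product)
                    if key in table:
                        return table[key]
        raise KeyError(
            f"no {self.source} entry for region={region!r} animal={animal!r} "
            f"system={system!r} climate={climate!r} product={product!r} "
            "and no default fallback"
        )

    def get_fcr(self, region: str, animal: str, system: str, climate: str,
                product: str) -> float:
        return self._lookup(self.fcr, region, animal, system, climate, product)

    def get_crff(self, region: str, animal: str, system: str, climate: str,
                 product: str) -> float:
        return self._lookup(self.crff, region, animal, system, climate, product)

    def protein(self, animal: str, product: str) -> float:
        """g protein per kg of product for a (species-group, product) pair."""
        if product == "milk":
            return self.protein_content["milk"]
        return self.protein_content[f"{animal}_meat"]


def _parse_feed_yaml(raw: dict) -> tuple[dict, dict]:
    def parse_table(entries):
        table = {}
        for e in entries or []:
            key = (
                e.get("region", "default"),
                e["animal"],
                e.get("system", "any"),
                e.get("climate", "any"),
                e["product"],
            )
            table[key] = float(e["value"])
        return table

    return parse_table(raw.get("fcr")), parse_table(raw.get("crff"))


def load_feed_params(source: str, path: str | Path | None = None) -> FeedParams:
    """Load one source's FCR/CRFF tables from YAML.

    Without ``path``, the packaged default table for ``source`` (one of
    ``herrero`` / ``mottet`` / ``mekonnen``) is used.  The mekonnen file has
    no CRFF block; the herrero CRFFs are substituted and the provenance
    recorded.
    """
    if path is None:
        ref = resources.files("resalloc.data") / f"feed_{source}.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    fcr, crff = _parse_feed_yaml(raw)
    provenance = source
    if not crff:
        if source != "mekonnen":
            raise ValueError(f"feed table for {source!r} lacks CRFF entries")
        herrero = load_feed_params("herrero")
        crff = dict(herrero.crff)
        provenance = "herrero"
    protein = raw.get("protein_content", PROTEIN_CONTENT)
    return FeedParams(
        source=source,
        fcr=fcr,
        crff=crff,
        protein_content={k: float(v) for k, v in protein.items()},
        crff_provenance=provenance,
    )


@dataclass
class BeddingRates:
    """Per-head straw usage for bedding, kg/day, plus horse chewing.

    Horse chewing straw is an additional 420 kg per head per year.  Poultry
    bedding is excluded (industrial farms use other materials such as
    sawdust), so poultry carries an implicit rate of zero.
    """

    cattle: float = 0.375
    sheep_goat: float = 0.1
    horse: float = 1.5
    pig: float = 0.0625
    horse_chewing_kg_yr: float = 420.0

    def __post_init__(self) -> None:
        for name in ("cattle", "sheep_goat", "horse", "pig", "horse_chewing_kg_yr"):
            if getattr(self, name) < 0:
                raise ValueError(f"bedding rate {name} must be non-negative")

    def daily(self, species: str) -> float:
        return {"cattle": self.cattle, "sheep_goat": self.sheep_goat,
                "horse": self.horse, "pig": self.pig}.get(species, 0.0)


# ---------------------------------------------------------------------------
# Allocation constants
# ---------------------------------------------------------------------------


@dataclass
class AllocationParams:
    """Caps and thresholds closing the per-cell mass balance.

    * ``removal_cap`` — at most this fraction of produced residues may leave
      the field through all uses combined (and burning + animal usage alone
      may not exceed it; a cell above it is a trade deficit cell).
    * ``min_left_fraction`` — complement of the cap: residues that always
      stay on the field because complete removal is impractical.
    * ``trade_radius_cells`` — maximum Chebyshev distance, in grid cells,
      over which deficit cells may import surplus residues.
    * ``other_use_poor`` / ``other_use_rich`` — upper bounds on the
      other-off-field-use fraction in low/high income countries, linearly
      interpolated in GDP per capita between ``gdp_poor_threshold`` and
      ``gdp_rich_threshold`` (2015 US$, the World Bank income-class limits).
    * ``max_return`` — regional caps on the fraction left on the field;
      excess is reassigned to other off-field uses.
    * ``residue_energy_mj_per_kg`` — lower heating value of cereal straw,
      used only for the domestic-fuel energy cross-check.
    """

    removal_cap: float = 0.90
    min_left_fraction: float = 0.10
    trade_radius_cells: int = 20
    other_use_poor: float = 0.30
    other_use_rich: float = 0.10
    gdp_poor_threshold: float = 1046.0
    gdp_rich_threshold: float = 12735.0
    max_return: dict[str, float] = dfield(
        default_factory=lambda: {
            "china": 0.60,
            "europe": 0.70,
            "north_america_oceania": 0.80,
        }
    )
    residue_energy_mj_per_kg: float = 18.0

    def __post_init__(self) -> None:
        if not 0 < self.removal_cap < 1:
            raise ValueError("removal_cap must lie in (0, 1)")
        if abs(self.min_left_fraction - (1 - self.removal_cap)) > 1e-9:
            raise ValueError("min_left_fraction must equal 1 - removal_cap")
        if not self.gdp_poor_threshold < self.gdp_rich_threshold:
            raise ValueError("GDP thresholds must satisfy poor < rich")
        for name in ("other_use_poor", "other_use_rich"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for region, m in self.max_return.items():
            if not 0 < m < 1:
                raise ValueError(f"max_return[{region}] must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AllocationParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Worked-example constants
# ---------------------------------------------------------------------------

#: Mean meridional km per degree of latitude (Earth circumference / 360°).
KM_PER_DEGREE = 40007.86 / 360.0


def china_domestic_fuel_share(
    energy_ej: float = 4.0,
    energy_content_mj_per_kg: float = 18.0,
    residue_production_tg: float = 730.0,
) -> float:
    """Fraction of residue production used as domestic fuel, in percent.

    The mid-1990s China cross-check behind the 30 % poor-country bound on
    other off-field uses: ~4 EJ/yr of domestic crop-residue burning, at
    18 MJ/kg, against ~730 Tg/yr of residue production.
    """
    mass_tg = energy_ej * 1e12 / energy_content_mj_per_kg / 1e9  # MJ / (MJ/kg) -> Tg
    return 100.0 * mass_tg / residue_production_tg


def trade_radius_km(
    radius_cells: int = 20, resolution_deg: float = 0.5
) -> float:
    """Trade search radius expressed in km at the equator (~1000 km)."""
    return radius_cells * resolution_deg * KM_PER_DEGREE
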