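"""Domain types for a farm-year and stocking computations.

A farm is described for a single simulation horizon of one year: land
parcels with their crops and fertilization, a herd inventory by animal
class, the purchase ledger, milk and meat sold, a grazing schedule and
twelve months of climate.  All downstream modules (nutrition, manure,
emissions, assessment) consume a validated :class:`FarmConfig`.
"""

from __future__ import annotations

import enum
from typing import Mapping

import numpy as np
from pydantic import BaseModel, Field, model_validator


class BreedGroup(str, enum.Enum):
    """The three breed groups simulated: the autochthonous Manchega dairy
    sheep, foreign dairy sheep (Lacaune and Assaf), and the Florida dairy
    goat."""

    MANCHEGA = "Manchega"
    FOREIGNERS = "Foreigners"
    FLORIDA = "Florida"

    @property
    def species(self) -> str:
        return "goat" if self is BreedGroup.FLORIDA else "sheep"


class Crop(str, enum.Enum):
    BARLEY_GRAIN = "barley_grain"
    OATS_FORAGE = "oats_forage"
    TRITICALE_FORAGE = "triticale_forage"
    VETCH_OAT = "vetch_oat"
    MAIZE_SILAGE = "maize_silage"
    ALFALFA = "alfalfa"
    LEGUMES = "legumes"
    FALLOW = "fallow"


class ForageUse(str, enum.Enum):
    HAY = "hay"
    SILAGE_BAG = "silage_bag"
    SILAGE_ROUND_BALE = "silage_round_bale"
    GRAZING = "grazing"
    GRAIN = "grain"


class LandParcel(BaseModel):
    """One cultivated (or fallow) block with its crop, area and fertilization."""

    crop: Crop
    area_ha: float = Field(ge=0)
    yield_t_dm_ha: float = Field(default=0.0, ge=0)
    use: ForageUse = ForageUse.HAY
    fert_n: float = Field(default=0.0, ge=0, description="kg N/ha")
    fert_p: float = Field(default=0.0, ge=0, description="kg P/ha")
    fert_k: float = Field(default=0.0, ge=0, description="kg K/ha")

    @property
    def production_kg_dm(self) -> float:
        return self.area_ha * self.yield_t_dm_ha * 1000.0


class HerdInventory(BaseModel):
    """Animal counts by production class and class mean live weights.

    ``present_females`` (PF) is the total breeding-female census driving the
    demography sub-models; lactating animals are split into high-, medium-
    and low-production batches.  ``genetic_value`` is the milk genetic index
    of the flock (national flock scale).
    """

    present_females: float = Field(ge=0)
    lactating_high: float = Field(default=0.0, ge=0)
    lactating_medium: float = Field(default=0.0, ge=0)
    lactating_low: float = Field(default=0.0, ge=0)
    non_lactating: float = Field(default=0.0, ge=0)
    replacement_0_4: float = Field(default=0.0, ge=0)
    replacement_4_12: float = Field(default=0.0, ge=0)
    studs: float = Field(default=0.0, ge=0)
    offspring: float = Field(default=0.0, ge=0)
    live_weight_kg: Mapping[str, float] = Field(default_factory=dict)
    genetic_value: float = 0.0

    @model_validator(mode="after")
    def _lactating_within_pf(self) -> "HerdInventory":
        lact = self.lactating_high + self.lactating_medium + self.lactating_low
        if lact > self.present_females * (1 + 1e-9):
            raise ValueError(
                f"lactating subtotal {lact:.1f} exceeds present females "
                f"{self.present_females:.1f}"
            )
        return self

    @property
    def lactating(self) -> float:
        return self.lactating_high + self.lactating_medium + self.lactating_low

    @property
    def adults(self) -> float:
        return self.present_females + self.studs

    @property
    def replacements(self) -> float:
        return self.replacement_0_4 + self.replacement_4_12

    def class_counts(self) -> dict[str, float]:
        return {
            "lactating_high": self.lactating_high,
            "lactating_medium": self.lactating_medium,
            "lactating_low": self.lactating_low,
            "non_lactating": self.non_lactating,
            "replacement_0_4": self.replacement_0_4,
            "replacement_4_12": self.replacement_4_12,
            "studs": self.studs,
            "offspring": self.offspring,
        }


class ClimateMonth(BaseModel):
    """Monthly climate record; ``etc_mm`` is the crop evapotranspiration
    computed externally (e.g. by a crop-water model) and supplied as input."""

    t_max: float
    t_min: float
    rainfall_mm: float = Field(ge=0)
    relative_humidity_pct: float = Field(default=60.0, ge=0, le=100)
    etc_mm: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _tmax_ge_tmin(self) -> "ClimateMonth":
        if self.t_max < self.t_min:
            raise ValueError(f"t_max {self.t_max} < t_min {self.t_min}")
        return self


class PurchaseLedger(BaseModel):
    """Annual purchased goods; every item maps to an embedded-CO2 factor."""

    forage_kg: float = Field(default=0.0, ge=0)
    concentrate_kg: float = Field(default=0.0, ge=0)
    soybean_kg: float = Field(default=0.0, ge=0)
    fertilizer_n_kg: float = Field(default=0.0, ge=0)
    fertilizer_p2o5_kg: float = Field(default=0.0, ge=0)
    fertilizer_k2o_kg: float = Field(default=0.0, ge=0)
    diesel_L: float = Field(default=0.0, ge=0)
    electricity_kwh: float = Field(default=0.0, ge=0)
    plastic_kg: float = Field(default=0.0, ge=0)
    animals_liveweight_kg: float = Field(default=0.0, ge=0)
    pesticide_treated_ha: float = Field(default=0.0, ge=0)
    milk_replacer_kg: float = Field(default=0.0, ge=0)
    bedding_straw_kg: float = Field(default=0.0, ge=0)


class FarmConfig(BaseModel):
    """Complete description of one farm-year."""

    breed_group: BreedGroup
    land: list[LandParcel] = Field(default_factory=list)
    communal_pasture_ha: float = Field(default=0.0, ge=0)
    herd: HerdInventory
    purchases: PurchaseLedger = Field(default_factory=PurchaseLedger)
    grazing_time_fraction: float = Field(default=0.0, ge=0, le=1)
    milking_time_min: float = Field(default=120.0, ge=0)
    milk_sold_L: float = Field(default=0.0, ge=0)
    milk_fat_pct: float = Field(default=6.5, gt=0, lt=15)
    milk_protein_pct: float = Field(default=5.8, gt=0, lt=15)
    live_weight_sold_kg: float = Field(default=0.0, ge=0)
    wool_sold_kg: float = Field(default=0.0, ge=0)
    manure_sold_kg: float = Field(default=0.0, ge=0)
    bedding_straw_kg_per_female: float = Field(default=225.0, ge=0)
    climate: list[ClimateMonth] = Field(default_factory=list)

    @model_validator(mode="after")
    def _twelve_months(self) -> "FarmConfig":
        if self.climate and len(self.climate) != 12:
            raise ValueError(f"climate must have 12 months, got {len(self.climate)}")
        return self

    @property
    def arable_ha(self) -> float:
        return sum(p.area_ha for p in self.land)

    @property
    def total_ha(self) -> float:
        return self.arable_ha + self.communal_pasture_ha

    @property
    def milk_suckled_L(self) -> float:
        # 35-day offspring lactation at 1 L/head/day
        return self.herd.offspring * 35.0

    @property
    def milk_total_L(self) -> float:
        return self.milk_sold_L + self.milk_suckled_L


class ConfigurationError(ValueError):
    """Raised when a coefficient table does not cover the farm description."""


DEFAULT_LU_TABLE: dict[str, float] = {
    # Adult small ruminants 0.15 LU, replacements 0.09, lambs/kids 0.05.
    # Conversion factors are a stated assumption (standard EU small-ruminant
    # coefficients), user-overridable via CSV.
    "lactating_high": 0.15,
    "lactating_medium": 0.15,
    "lactating_low": 0.15,
    "non_lactating": 0.15,
    "studs": 0.15,
    "replacement_0_4": 0.09,
    "replacement_4_12": 0.09,
    "offspring": 0.05,
}


def livestock_units(
    herd: HerdInventory, lu_table: Mapping[str, float] | None = None
) -> float:
    """Herd size in livestock units: sum of class count x class coefficient.

    Raises :class:`ConfigurationError` naming the class if a populated class
    has no coefficient.
    """
    table = DEFAULT_LU_TABLE if lu_table is None else lu_table
    total = 0.0
    for cls, count in herd.class_counts().items():
        if count == 0:
            continue
        if cls not in table:
            raise ConfigurationError(f"no livestock-unit coefficient for class {cls!r}")
        total += count * table[cls]
    return total


def stocking_density(lu: float, area_ha: float) -> float:
    """Stocking level in livestock units per hectare."""
    if area_ha <= 0:
        raise ValueError("stocking density undefined for zero area")
    return lu / area_ha


def validate_farm(farm: FarmConfig) -> list[str]:
    """Structural checks beyond field validation; returns a list of problems
    (empty when the farm is consistent)."""
    problems: list[str] = []
    if not farm.land and farm.communal_pasture_ha == 0:
        problems.append("farm has no land (no parcels, no communal pasture)")
    if farm.milk_sold_L > 0 and farm.herd.lactating == 0:
        problems.append("milk sold but no lactating animals")
    total_fert_n = sum(p.fert_n * p.area_ha for p in farm.land)
    if total_fert_n > 0 and farm.purchases.fertilizer_n_kg == 0:
        # applied-but-unpurchased N is legal (carry-over) but worth flagging
        problems.append("fertilizer N applied on parcels but none purchased")
    if farm.climate:
        gdd_year = sum(
            max(0.0, (m.t_max + m.t_min) / 2 - 4.0) for m in farm.climate
        )
        if gdd_year == 0:
            problems.append("annual growing degree-days are zero")
    if not np.isfinite(farm.milk_sold_L):
        problems.append("milk_sold_L is not finite")
    return problems
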