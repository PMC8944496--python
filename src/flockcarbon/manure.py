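"""Manure production and nutrient balances.

Housed manure is feces + urine + bedding minus the share deposited
directly on pasture while grazing and minus any manure sold.  Farm-gate
nitrogen and phosphorus balances follow the input-output convention:
surplus = inputs - outputs exactly, efficiency = 100 x outputs / inputs,
both expressed per hectare of farmland.
"""

from __future__ import annotations

from dataclasses import dataclass

from .farm import FarmConfig

# N, P, K concentration of fresh manure deposited while grazing (mass
# fractions of fresh weight)
GRAZING_N_FRAC = 0.0055
GRAZING_P_FRAC = 0.0007
GRAZING_K_FRAC = 0.011

# Housed (stored solid) manure concentrations; defaults for solid
# sheep/goat manure, user-overridable
HOUSED_P_FRAC = 0.0012
HOUSED_K_FRAC = 0.009

# Per-kg-liveweight nutrient contents of animals
ANIMAL_N_PER_KG_LW = 0.28
ANIMAL_P_PER_KG_LW = 0.0065

ATMOSPHERIC_N_KG_HA = 10.0
MILK_DENSITY_KG_L = 1.034  # to convert protein % (mass) to per-liter N
MILK_P_G_PER_L = 1.3
WOOL_N_FRAC = 0.128
WOOL_P_G_PER_KG = 0.1
CP_TO_N = 6.38  # milk crude protein to N divisor

# Symbiotic N fixation, kg N/ha/yr by crop (literature defaults)
LEGUME_FIXATION_KG_N_HA = {
    "alfalfa": 150.0,
    "legumes": 60.0,
    "vetch_oat": 60.0,
}

P2O5_TO_P = 0.4364
K2O_TO_K = 0.8301


@dataclass(frozen=True)
class ManureBudget:
    """Annual manure pools (kg fresh weight unless noted)."""

    feces_kg_dm: float
    urine_L: float
    bedding_kg: float
    grazing_share: float
    sold_kg: float
    housed_kg: float
    pasture_kg: float
    n_total_kg: float
    n_housed_kg: float
    n_pasture_kg: float
    p_kg: float
    k_kg: float

    @property
    def produced_kg(self) -> float:
        return self.housed_kg + self.pasture_kg + self.sold_kg


def manure_budget(
    feces_kg_dm: float,
    urine_L: float,
    n_excreted_kg: float,
    bedding_kg: float,
    grazing_share: float,
    sold_kg: float = 0.0,
    feces_dm_fraction: float = 0.35,
) -> ManureBudget:
    """Partition annual excreta + bedding into housed, pasture and sold
    pools.  ``grazing_share`` is the fraction of excreta deposited on
    pasture (bedding is always housed); manure DM is 35% by convention.
    """
    if not 0 <= grazing_share <= 1:
        raise ValueError("grazing_share must be in [0, 1]")
    feces_fresh = feces_kg_dm / feces_dm_fraction
    excreta_fresh = feces_fresh + urine_L  # urine ~1 kg/L
    pasture = excreta_fresh * grazing_share
    housed_before_sale = excreta_fresh * (1 - grazing_share) + bedding_kg
    if sold_kg > housed_before_sale + 1e-9:
        raise ValueError(
            f"manure sold ({sold_kg:.0f} kg) exceeds housed production "
            f"({housed_before_sale:.0f} kg)"
        )
    housed = housed_before_sale - sold_kg
    n_pasture = n_excreted_kg * grazing_share
    n_housed = n_excreted_kg * (1 - grazing_share)
    p_kg = pasture * GRAZING_P_FRAC + (housed + sold_kg) * HOUSED_P_FRAC
    k_kg = pasture * GRAZING_K_FRAC + (housed + sold_kg) * HOUSED_K_FRAC
    return ManureBudget(
        feces_kg_dm=feces_kg_dm,
        urine_L=urine_L,
        bedding_kg=bedding_kg,
        grazing_share=grazing_share,
        sold_kg=sold_kg,
        housed_kg=housed,
        pasture_kg=pasture,
        n_total_kg=n_excreted_kg,
        n_housed_kg=n_housed,
        n_pasture_kg=n_pasture,
        p_kg=p_kg,
        k_kg=k_kg,
    )


def grazing_manure_nutrients(fresh_kg: float) -> dict[str, float]:
    """N, P, K (kg) in fresh manure deposited while grazing."""
    return {
        "n_kg": fresh_kg * GRAZING_N_FRAC,
        "p_kg": fresh_kg * GRAZING_P_FRAC,
        "k_kg": fresh_kg * GRAZING_K_FRAC,
    }


@dataclass(frozen=True)
class NutrientBalance:
    """Farm-gate balance for one element, per hectare of farmland."""

    element: str
    inputs_kg_ha: float
    outputs_kg_ha: float
    items: dict[str, float]

    @property
    def surplus_kg_ha(self) -> float:
        return self.inputs_kg_ha - self.outputs_kg_ha

    @property
    def efficiency_pct(self) -> float:
        if self.inputs_kg_ha == 0:
            raise ZeroDivisionError(
                f"{self.element} efficiency undefined: zero inputs"
            )
        return 100.0 * self.outputs_kg_ha / self.inputs_kg_ha


def milk_n_kg(liters: float, protein_pct: float) -> float:
    """Milk N: crude protein mass divided by 6.38, milk density 1.034 kg/L."""
    return liters * MILK_DENSITY_KG_L * protein_pct / 100.0 / CP_TO_N


def farm_n_p_balance(
    farm: FarmConfig,
    feed_n_fraction: dict[str, float] | None = None,
    feed_p_fraction: dict[str, float] | None = None,
    bedding_n_fraction: float = 0.006,
    bedding_p_fraction: float = 0.0008,
    manure_sold_n_fraction: float = 0.0055,
) -> dict[str, NutrientBalance]:
    """Farm-gate N and P balances (kg/ha of total farmland).

    Inputs: purchased feed, fertilizers, purchased animals, atmospheric
    deposition, purchased bedding straw and symbiotic fixation by legume
    crops.  Outputs: milk (CP/6.38; 1.3 g P/L), meat (0.28 kg N and
    0.0065 kg P per kg liveweight), wool (12.8% N; 0.1 g P/kg) and sold
    manure.  Per-item contributions are returned for auditing.
    """
    area = farm.total_ha
    if area <= 0:
        raise ValueError("farm has zero area; per-hectare balance undefined")
    n_frac = {"forage": 0.0192, "concentrate": 0.0288, "soybean": 0.0704,
              "milk_replacer": 0.0352}
    p_frac = {"forage": 0.0025, "concentrate": 0.0045, "soybean": 0.0062,
              "milk_replacer": 0.007}
    if feed_n_fraction:
        n_frac.update(feed_n_fraction)
    if feed_p_fraction:
        p_frac.update(feed_p_fraction)
    p = farm.purchases

    n_in = {
        "purchased_forage": p.forage_kg * n_frac["forage"],
        "purchased_concentrate": p.concentrate_kg * n_frac["concentrate"],
        "purchased_soybean": p.soybean_kg * n_frac["soybean"],
        "milk_replacer": p.milk_replacer_kg * n_frac["milk_replacer"],
        "fertilizer": p.fertilizer_n_kg,
        "purchased_animals": p.animals_liveweight_kg * ANIMAL_N_PER_KG_LW,
        "atmospheric": ATMOSPHERIC_N_KG_HA * area,
        "bedding_straw": p.bedding_straw_kg * bedding_n_fraction,
        "legume_fixation": sum(
            LEGUME_FIXATION_KG_N_HA.get(parcel.crop.value, 0.0) * parcel.area_ha
            for parcel in farm.land
        ),
    }
    n_out = {
        "milk": milk_n_kg(farm.milk_sold_L, farm.milk_protein_pct),
        "meat": farm.live_weight_sold_kg * ANIMAL_N_PER_KG_LW,
        "wool": farm.wool_sold_kg * WOOL_N_FRAC,
        "manure_sold": farm.manure_sold_kg * manure_sold_n_fraction,
    }
    p_in = {
        "purchased_forage": p.forage_kg * p_frac["forage"],
        "purchased_concentrate": p.concentrate_kg * p_frac["concentrate"],
        "purchased_soybean": p.soybean_kg * p_frac["soybean"],
        "milk_replacer": p.milk_replacer_kg * p_frac["milk_replacer"],
        "fertilizer": p.fertilizer_p2o5_kg * P2O5_TO_P,
        "purchased_animals": p.animals_liveweight_kg * ANIMAL_P_PER_KG_LW,
        "bedding_straw": p.bedding_straw_kg * bedding_p_fraction,
    }
    p_out = {
        "milk": farm.milk_sold_L * MILK_P_G_PER_L / 1000.0,
        "meat": farm.live_weight_sold_kg * ANIMAL_P_PER_KG_LW,
        "wool": farm.wool_sold_kg * WOOL_P_G_PER_KG / 1000.0,
        "manure_sold": farm.manure_sold_kg * HOUSED_P_FRAC,
    }

    def per_ha(d: dict[str, float]) -> dict[str, float]:
        return {k: v / area for k, v in d.items()}

    balances = {}
    for element, ins, outs in (("N", n_in, n_out), ("P", p_in, p_out)):
        items = {**{f"in_{k}": v for k, v in per_ha(ins).items()},
                 **{f"out_{k}": v for k, v in per_ha(outs).items()}}
        balances[element] = NutrientBalance(
            element=element,
            inputs_kg_ha=sum(ins.values()) / area,
            outputs_kg_ha=sum(outs.values()) / area,
            items=items,
        )
    return balances


@dataclass(frozen=True)
class SoilBalance:
    element: str
    inputs_kg_ha: float
    outputs_kg_ha: float
    extractions_kg_ha: float
    residues_kg_ha: float

    @property
    def balance_kg_ha(self) -> float:
        return self.inputs_kg_ha - self.outputs_kg_ha

    @property
    def efficiency_pct(self) -> float:
        """Soil utilization efficiency:
        100 x (extractions - residues) / (inputs - balance)."""
        denom = self.inputs_kg_ha - self.balance_kg_ha
        if denom == 0:
            raise ZeroDivisionError(
                f"soil {self.element} efficiency undefined: inputs equal balance"
            )
        return 100.0 * (self.extractions_kg_ha - self.residues_kg_ha) / denom


def soil_balance(
    element: str,
    inputs_kg_ha: float,
    gaseous_losses_kg_ha: float,
    leaching_kg_ha: float,
    extractions_kg_ha: float,
    residues_kg_ha: float = 0.0,
) -> SoilBalance:
    """Soil nutrient balance: inputs minus (gaseous + leached + extracted)."""
    if inputs_kg_ha < 0:
        raise ValueError("inputs must be non-negative")
    outputs = gaseous_losses_kg_ha + leaching_kg_ha + extractions_kg_ha
    return SoilBalance(
        element=element,
        inputs_kg_ha=inputs_kg_ha,
        outputs_kg_ha=outputs,
        extractions_kg_ha=extractions_kg_ha,
        residues_kg_ha=residues_kg_ha,
    )
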