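"""Footprint synthesis: fat-and-protein-corrected milk, milk/meat
allocation, carbon footprint per functional unit, acidification and
eutrophication potentials, water/energy/nitrogen footprints and land use.

Functional units: one hectare, one livestock unit, one present female and
one liter of FPCM (reference composition 6.5% fat, 5.8% protein).
The partial carbon footprint PCF sums all operational pathways; the total
TCF adds the soybean chain (SY) and indirect land-use change (iLUC) and
subtracts carbon sequestration (CS): TCF = PCF + SY + iLUC - CS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# FPCM correction: liters x (0.25 + 0.085 x fat% + 0.035 x protein%);
# normalizes to ~1 at the 6.5/5.8 reference composition
FPCM_BASE = 0.25
FPCM_FAT = 0.085
FPCM_PROTEIN = 0.035

ALLOCATION_SLOPE = 5.7717  # AF = 1 - 5.7717 x (meat mass / milk mass)

# Acidification (SO2 equivalents) and eutrophication (NO3 equivalents)
AP_SO2 = 1.0
AP_NOX = 0.7
AP_NH3 = 1.89
EP_NO3 = 1.0
EP_NOX = 1.35
EP_NH3 = 3.64
EP_PO4 = 10.45

CLEANING_WATER_L_PER_L_MILK = 2.2
DRINKING_WATER_L_HEAD_DAY = {"sheep": 7.0, "goat": 8.0}

# Direct energy densities
DIESEL_MJ_PER_L = 35.9
ELECTRICITY_MJ_PER_KWH = 3.6

# Indirect energy, MJ per unit purchased (literature defaults)
ENERGY_MJ_PER_UNIT = {
    "fertilizer_n_kg": 48.99,
    "fertilizer_p2o5_kg": 15.23,
    "fertilizer_k2o_kg": 9.68,
    "concentrate_kg": 3.5,
    "forage_kg": 2.0,
    "soybean_kg": 4.0,
    "plastic_kg": 75.0,
    "milk_replacer_kg": 30.0,
}

# Off-farm reference yields for purchased products, t/ha
OFF_FARM_YIELD_T_HA = {
    "barley": 2.9,
    "rapeseed": 2.5,
    "corn": 10.6,
    "soybean": 2.9,
    "beetroot_pulp": 4.7,
    "cottonseed": 4.4,
    "sugarcane_molasses": 1.3,
    "palm_oil": 3.0,
    "alfalfa": 11.3,
    "cereal_straw": 2.5,
    # composite purchased concentrate / forage treated as barley / alfalfa-like
    "concentrate": 2.9,
    "forage": 4.0,
}

# Green/blue/grey water of imported products, m3 per tonne
WATER_M3_PER_T = {
    "concentrate": {"green": 1000.0, "blue": 150.0, "grey": 200.0},
    "forage": {"green": 500.0, "blue": 100.0, "grey": 80.0},
    "soybean": {"green": 2000.0, "blue": 100.0, "grey": 30.0},
    "milk_replacer": {"green": 1500.0, "blue": 300.0, "grey": 250.0},
}


def fpcm(liters: float, fat_pct: float, protein_pct: float) -> float:
    """Fat- and protein-corrected milk, liters."""
    if liters < 0:
        raise ValueError("liters must be non-negative")
    return liters * (FPCM_BASE + FPCM_FAT * fat_pct + FPCM_PROTEIN * protein_pct)


def allocation_factor(m_meat_kg_ha: float, m_milk_kg_ha: float) -> dict[str, float]:
    """Milk/meat co-product allocation: R = meat/milk mass ratio,
    AF = clamp(1 - 5.7717 R, 0, 1).  Milk carries AF of total emissions."""
    if m_milk_kg_ha <= 0:
        raise ValueError("meat-only farms unsupported: milk mass must be positive")
    r = m_meat_kg_ha / m_milk_kg_ha
    af = min(1.0, max(0.0, 1.0 - ALLOCATION_SLOPE * r))
    return {"R": r, "AF": af}


def impact_potentials(
    so2_kg: float = 0.0,
    nox_kg: float = 0.0,
    nh3_kg: float = 0.0,
    no3_kg: float = 0.0,
    po4_kg: float = 0.0,
) -> dict[str, float]:
    """Acidification (kg SO2e) and eutrophication (kg NO3e) potentials."""
    for v in (so2_kg, nox_kg, nh3_kg, no3_kg, po4_kg):
        if v < 0:
            raise ValueError("masses must be non-negative")
    return {
        "ap_kg_so2e": AP_SO2 * so2_kg + AP_NOX * nox_kg + AP_NH3 * nh3_kg,
        "ep_kg_no3e": EP_NO3 * no3_kg + EP_NOX * nox_kg + EP_NH3 * nh3_kg
        + EP_PO4 * po4_kg,
    }


def land_use(
    off_farm_feed_kg: dict[str, float],
    on_farm_area_m2: float,
    fpcm_L: float,
) -> dict[str, float]:
    """Land occupation in m2 per liter of FPCM, split on/off farm.

    Off-farm area for each purchased product is its mass divided by the
    reference yield (t/ha) of that product's cropping system.
    """
    if fpcm_L <= 0:
        raise ValueError("fpcm_L must be positive")
    off_m2 = 0.0
    for product, kg in off_farm_feed_kg.items():
        if kg == 0:
            continue
        try:
            yield_t_ha = OFF_FARM_YIELD_T_HA[product]
        except KeyError:
            raise KeyError(f"no reference yield for product {product!r}")
        off_m2 += kg / (yield_t_ha * 1000.0) * 10000.0
    return {
        "on_m2_per_L": on_farm_area_m2 / fpcm_L,
        "off_m2_per_L": off_m2 / fpcm_L,
        "total_m2_per_L": (on_farm_area_m2 + off_m2) / fpcm_L,
        "off_m2": off_m2,
    }


@dataclass
class FootprintReport:
    """All per-farm footprints; CO2e entries on each functional unit."""

    pcf_kg_co2e: float
    sy_kg_co2e: float
    iluc_kg_co2e: float
    cs_kg_co2e: float
    af: float
    r: float
    fpcm_L: float
    per_fu: dict[str, float] = field(default_factory=dict)
    ap_kg_so2e: float = 0.0
    ep_kg_no3e: float = 0.0
    wf_green: float = 0.0
    wf_blue: float = 0.0
    wf_grey: float = 0.0
    wf_drinking: float = 0.0
    wf_cleaning: float = 0.0
    ef_direct_mj: float = 0.0
    ef_indirect_mj: float = 0.0
    nf_total_kg_n: float = 0.0
    nf_reactive_kg_n: float = 0.0
    land_use_on_m2_L: float = 0.0
    land_use_off_m2_L: float = 0.0

    @property
    def tcf_kg_co2e(self) -> float:
        return self.pcf_kg_co2e + self.sy_kg_co2e + self.iluc_kg_co2e - self.cs_kg_co2e

    @property
    def wf_total_m3(self) -> float:
        return (self.wf_green + self.wf_blue + self.wf_grey
                + self.wf_drinking + self.wf_cleaning)

    @property
    def wf_partial_m3(self) -> float:
        """Partial water footprint: blue + grey."""
        return self.wf_blue + self.wf_grey

    @property
    def ef_total_mj(self) -> float:
        return self.ef_direct_mj + self.ef_indirect_mj

    @property
    def land_use_total_m2_L(self) -> float:
        return self.land_use_on_m2_L + self.land_use_off_m2_L


def carbon_footprint_report(
    pcf: float,
    sy: float,
    iluc: float,
    cs: float,
    area_ha: float,
    lu: float,
    present_females: float,
    fpcm_L: float,
    meat_kg_ha: float,
    milk_kg_ha: float,
) -> FootprintReport:
    """Assemble the CO2e slice of the report: TCF identity and the four
    functional units.  The liter-of-FPCM unit carries the milk share (AF)
    of the total footprint; per-hectare, per-LU and per-female report the
    unallocated total."""
    alloc = allocation_factor(meat_kg_ha, milk_kg_ha)
    report = FootprintReport(
        pcf_kg_co2e=pcf, sy_kg_co2e=sy, iluc_kg_co2e=iluc, cs_kg_co2e=cs,
        af=alloc["AF"], r=alloc["R"], fpcm_L=fpcm_L,
    )
    tcf = report.tcf_kg_co2e
    report.per_fu = {
        "ha": tcf / area_ha if area_ha > 0 else math.nan,
        "LU": tcf / lu if lu > 0 else math.nan,
        "present_female": tcf / present_females if present_females > 0 else math.nan,
        "L_FPCM": tcf * alloc["AF"] / fpcm_L if fpcm_L > 0 else math.nan,
    }
    return report


def water_footprint(
    crop_water_m3: float,
    imported_kg: dict[str, float],
    milk_L: float,
    heads: float,
    species: str = "sheep",
) -> dict[str, float]:
    """Green/blue/grey water (m3) of the farm: on-farm crop water (treated
    as green), imported-product water by class, drinking water per head and
    cleaning water at 2.2 L per liter of milk."""
    green = crop_water_m3
    blue = grey = 0.0
    for product, kg in imported_kg.items():
        if kg == 0:
            continue
        try:
            w = WATER_M3_PER_T[product]
        except KeyError:
            raise KeyError(f"no water-footprint factors for product {product!r}")
        green += kg / 1000.0 * w["green"]
        blue += kg / 1000.0 * w["blue"]
        grey += kg / 1000.0 * w["grey"]
    drinking = heads * DRINKING_WATER_L_HEAD_DAY[species] * 365.0 / 1000.0
    cleaning = milk_L * CLEANING_WATER_L_PER_L_MILK / 1000.0
    return {"green": green, "blue": blue, "grey": grey,
            "drinking": drinking, "cleaning": cleaning}


def energy_footprint(
    diesel_L: float, electricity_kwh: float, purchases_units: dict[str, float]
) -> dict[str, float]:
    """Direct (fuel + electricity) and indirect (embedded in purchases)
    energy footprint, MJ."""
    direct = diesel_L * DIESEL_MJ_PER_L + electricity_kwh * ELECTRICITY_MJ_PER_KWH
    indirect = 0.0
    for item, units in purchases_units.items():
        indirect += ENERGY_MJ_PER_UNIT.get(item, 0.0) * units
    return {"direct_mj": direct, "indirect_mj": indirect}
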