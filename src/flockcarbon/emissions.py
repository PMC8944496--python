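"""Gas flows: enteric and manure CH4, ammonia, direct and indirect N2O,
embedded CO2 of purchased goods, silage CO2, and soil carbon sequestration,
collected in an additive :class:`EmissionLedger` and aggregated to CO2
equivalents (CH4 x 28, N2O x 298).

Factor conventions: factors printed as kg N2O-N per kg N are converted to
N2O mass at ledger entry with the 44/28 molar ratio; factors stated
directly as N2O (e.g. 0.0015 kg N2O per kg NH3) are not converted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .farm import PurchaseLedger

GWP = {"CH4": 28.0, "N2O": 298.0, "CO2": 1.0}
N2O_N_TO_N2O = 44.0 / 28.0
NH3_TO_N = 14.0 / 17.0

GE_MJ_PER_KG = 18.55       # gross energy density of feed DM
CH4_ENERGY_MJ_PER_KG = 55.65
CH4_DENSITY_KG_M3 = 0.67

# N2O-N per kg N applied (soil direct) for manure / mineral fertilizer /
# crop residues; printed as "g N-N2O kg-1" but dimensionally these are the
# standard per-kg emission fractions (0.3%, 1%, 1%)
EF_SOIL_MANURE = 0.003
EF_SOIL_FERT = 0.01
EF_SOIL_RESIDUE = 0.01
EF_VOLATILIZED = 0.005   # kg N2O-N per kg volatile N
EF_LEACHED = 0.025       # kg N2O-N per kg leached N
EF_FERT_MANUFACTURE = 0.005   # kg N2O per kg fertilizer N (direct N2O mass)
EF_PURCHASED_FORAGE_N = 0.020  # kg N2O-N per kg purchased N
EF_PURCHASED_CONC_N = 0.010

NH3_EF_HOUSED = 0.1    # kg NH3 per kg excreted N in barns/heaps
NH3_EF_GRAZING = 0.12  # kg NH3 per kg excreted N while grazing
N2O_PER_NH3_HOUSED = 0.0015  # kg N2O per kg NH3 (direct N2O mass)
N2O_GRAZING = 0.025    # kg N2O per kg (excreted N - NH3) while grazing

# Embedded CO2 of purchases, kg CO2 per unit
CO2_DIESEL_L = 3.31
CO2_ELECTRICITY_KWH = 0.65
CO2_FERT_N = 6.2
CO2_FERT_P2O5 = 0.93
CO2_FERT_K2O = 0.51
CO2_FORAGE_KG = 0.2
CO2_CONCENTRATE_KG = 0.3
CO2_PLASTIC_KG = 2.0
CO2_ANIMAL_KG_LW = 11.0
CO2_PESTICIDE_HA = 22.2
CO2_MILK_REPLACER_KG = 9.73  # CO2e per kg of formula
CO2_SOYBEAN_KG = 2.98        # imported soybean chain
ILUC_CO2_KG_M2 = 0.143       # cultivated-area land-use-change charge

DIESEL_L_PER_LU = 37.0       # default when diesel purchases unreported
ELECTRICITY_KWH_PER_EWE_MIN = 0.2  # kWh/yr per lactating female per daily milking minute

# Silage
SILAGE_PLASTIC_BAG_KG_T = 0.68
SILAGE_PLASTIC_SMALL_SILO_KG = 1.3   # per silo
SMALL_SILO_CAPACITY_T = 10.0
SILAGE_PLASTIC_ROUND_BALE_KG_T = 1.2  # default, not printed
SILAGE_CO2_PER_KG_DM_LOST = 0.24
SILAGE_DM_LOSS = {"cereal": 0.123, "maize": 0.03}

# Carbon sequestration
PLANT_C_FRACTION = 0.45
MANURE_C_PER_N = 13.4
HUMIFICATION_DEFAULT = 0.1
CEREAL_STRAW_KG_DM_HA = 1758.0
MAIZE_RESIDUE_SHARE = 0.19
ALFALFA_RESIDUE_SHARE = 0.34


class Gas(str, enum.Enum):
    CH4 = "CH4"
    N2O = "N2O"
    CO2 = "CO2"


@dataclass(frozen=True)
class EmissionEntry:
    category: str
    gas: Gas
    kg: float

    @property
    def co2e(self) -> float:
        return self.kg * GWP[self.gas.value]


@dataclass
class EmissionLedger:
    """Append-only list of (category, gas, kg) entries.

    Sequestration is the only category allowed to carry negative mass
    (it is a removal).
    """

    entries: list[EmissionEntry] = field(default_factory=list)

    def add(self, category: str, gas: Gas | str, kg: float) -> None:
        gas = Gas(gas)
        if kg < 0 and category != "sequestration":
            raise ValueError(f"negative emission for {category}: {kg}")
        self.entries.append(EmissionEntry(category, gas, kg))

    def extend(self, other: "EmissionLedger") -> None:
        self.entries.extend(other.entries)

    def total(self, gas: Gas | str) -> float:
        gas = Gas(gas)
        return sum(e.kg for e in self.entries if e.gas is gas)

    def by_category(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.entries:
            out[e.category] = out.get(e.category, 0.0) + e.co2e
        return out

    def category_total(self, category: str) -> float:
        return sum(e.co2e for e in self.entries if e.category == category)


def co2e(ledger: EmissionLedger) -> float:
    """Total CO2 equivalents: CO2 + 28 x CH4 + 298 x N2O, preserving the
    sign of sequestration entries."""
    return sum(e.co2e for e in ledger.entries)


def ym(omd_pct: float) -> float:
    """Methane conversion factor Ym (% of gross energy) from diet
    organic-matter digestibility in percent: Ym = 9.75 - 0.05 x OMD."""
    if not 0 < omd_pct <= 100:
        raise ValueError(f"omd_pct must be in (0, 100], got {omd_pct}")
    if omd_pct <= 1:
        raise ValueError(
            f"omd_pct={omd_pct} looks fractional; pass percent (e.g. 63.3)"
        )
    return 9.75 - 0.05 * omd_pct


def enteric_ch4(dmi_g_per_day: float, ym_pct: float) -> float:
    """Enteric CH4 (g/head/day): DMI x (Ym/100) x (18.55/55.65)."""
    if dmi_g_per_day < 0:
        raise ValueError("dmi must be non-negative")
    return dmi_g_per_day * (ym_pct / 100.0) * (GE_MJ_PER_KG / CH4_ENERGY_MJ_PER_KG)


def manure_ch4(
    manure_dm_kg: float,
    b0_m3_per_kg_vs: float = 0.19,
    mcf_fraction: float = 0.02,
    vs_fraction: float = 0.8,
) -> float:
    """Manure-management CH4 (kg) via the DM -> volatile solids -> CH4
    chain: DM x VS x B0 x MCF x 0.67 kg/m3.  Defaults describe solid-stored
    sheep/goat manure (B0 0.19 m3 CH4/kg VS, MCF 2%, VS 80% of DM)."""
    for name, v in [("mcf_fraction", mcf_fraction), ("vs_fraction", vs_fraction)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    return manure_dm_kg * vs_fraction * b0_m3_per_kg_vs * mcf_fraction * CH4_DENSITY_KG_M3


def nh3_n2o_animal(
    n_excreted_housed_kg: float, n_excreted_grazing_kg: float
) -> dict[str, float]:
    """NH3 and N2O from barns/manure heaps and from grazing deposition.

    Housed: 0.1 kg NH3/kg N, then 0.0015 kg N2O per kg NH3.
    Grazing: 0.12 kg NH3/kg N, then 0.025 kg N2O per kg of (N - NH3).
    """
    if n_excreted_housed_kg < 0 or n_excreted_grazing_kg < 0:
        raise ValueError("excreted N must be non-negative")
    nh3_housing = NH3_EF_HOUSED * n_excreted_housed_kg
    nh3_grazing = NH3_EF_GRAZING * n_excreted_grazing_kg
    return {
        "nh3_housing": nh3_housing,
        "nh3_grazing": nh3_grazing,
        "n2o_housing": N2O_PER_NH3_HOUSED * nh3_housing,
        "n2o_grazing": N2O_GRAZING * (n_excreted_grazing_kg - nh3_grazing),
    }


def soil_n2o(
    applied_manure_n_kg: float = 0.0,
    fert_n_kg: float = 0.0,
    residue_n_kg: float = 0.0,
    volatilized_n_kg: float = 0.0,
    leached_n_kg: float = 0.0,
    purchased_forage_n_kg: float = 0.0,
    purchased_conc_n_kg: float = 0.0,
    purchased_fert_n_kg: float = 0.0,
) -> dict[str, float]:
    """N2O (kg of N2O mass) by pathway.

    Direct soil pathways (manure, fertilizer, residues) and the indirect
    volatilization/leaching and purchased-input pathways are N2O-N factors
    converted with 44/28; fertilizer manufacture (5 g N2O/kg N) is already
    N2O mass.
    """
    args = locals()
    for name, v in args.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return {
        "soil_manure": EF_SOIL_MANURE * applied_manure_n_kg * N2O_N_TO_N2O,
        "soil_fertilizer": EF_SOIL_FERT * fert_n_kg * N2O_N_TO_N2O,
        "soil_residue": EF_SOIL_RESIDUE * residue_n_kg * N2O_N_TO_N2O,
        "indirect_volatilization": EF_VOLATILIZED * volatilized_n_kg * N2O_N_TO_N2O,
        "indirect_leaching": EF_LEACHED * leached_n_kg * N2O_N_TO_N2O,
        "purchased_forage": EF_PURCHASED_FORAGE_N * purchased_forage_n_kg * N2O_N_TO_N2O,
        "purchased_concentrate": EF_PURCHASED_CONC_N * purchased_conc_n_kg * N2O_N_TO_N2O,
        "fertilizer_manufacture": EF_FERT_MANUFACTURE * purchased_fert_n_kg,
    }


def leached_no3(
    total_n_applied_kg: float,
    drainage_mm: float,
    max_fraction: float = 0.3,
    full_drainage_mm: float = 1000.0,
) -> float:
    """Leached NO3-N (kg) as a drainage-scaled fraction of applied N:
    lambda = min(max_fraction, drainage/full_drainage), zero without
    drainage.  Drainage is the annual sum of max(0, rainfall - ETc)."""
    if total_n_applied_kg < 0 or drainage_mm < 0:
        raise ValueError("inputs must be non-negative")
    lam = min(max_fraction, drainage_mm / full_drainage_mm)
    return lam * total_n_applied_kg


def drainage_mm(climate) -> float:
    """Annual drained water (mm): sum of monthly max(0, rainfall - ETc)."""
    return sum(max(0.0, m.rainfall_mm - m.etc_mm) for m in climate)


def embedded_co2(
    purchases: PurchaseLedger,
    lu: float = 0.0,
    lactating_females: float = 0.0,
    milking_time_min: float = 0.0,
) -> dict[str, float]:
    """Embedded CO2 (kg) of purchased goods and services, by item.

    Diesel defaults to 37 L/LU/yr when no purchase is reported; electricity
    defaults to a per-lactating-female, per-milking-minute coefficient when
    no kWh figure is reported.  Soybean is reported separately (it also
    enters the total carbon footprint as the SY add-on).
    """
    diesel_L = purchases.diesel_L if purchases.diesel_L > 0 else DIESEL_L_PER_LU * lu
    kwh = purchases.electricity_kwh
    if kwh == 0:
        kwh = ELECTRICITY_KWH_PER_EWE_MIN * lactating_females * milking_time_min
    return {
        "diesel": CO2_DIESEL_L * diesel_L,
        "electricity": CO2_ELECTRICITY_KWH * kwh,
        "fertilizer_n": CO2_FERT_N * purchases.fertilizer_n_kg,
        "fertilizer_p2o5": CO2_FERT_P2O5 * purchases.fertilizer_p2o5_kg,
        "fertilizer_k2o": CO2_FERT_K2O * purchases.fertilizer_k2o_kg,
        "forage": CO2_FORAGE_KG * purchases.forage_kg,
        "concentrate": CO2_CONCENTRATE_KG * purchases.concentrate_kg,
        "plastic": CO2_PLASTIC_KG * purchases.plastic_kg,
        "animals": CO2_ANIMAL_KG_LW * purchases.animals_liveweight_kg,
        "pesticides": CO2_PESTICIDE_HA * purchases.pesticide_treated_ha,
        "milk_replacer": CO2_MILK_REPLACER_KG * purchases.milk_replacer_kg,
    }


def silage_co2(
    mass_t: float, method: str, crop: str = "cereal", dm_fraction: float = 0.35
) -> dict[str, float]:
    """CO2 from ensiling ``mass_t`` tonnes of fresh silage: plastic
    manufacture (2 kg CO2/kg plastic) plus fermentation dry-matter loss
    (0.24 kg CO2/kg DM lost; 12.3% loss for cereal silage, 3% for maize)."""
    if mass_t < 0:
        raise ValueError("mass must be non-negative")
    if method == "bag":
        plastic_kg = SILAGE_PLASTIC_BAG_KG_T * mass_t
    elif method == "round_bale":
        plastic_kg = SILAGE_PLASTIC_ROUND_BALE_KG_T * mass_t
    elif method == "small_silo":
        import math
        plastic_kg = SILAGE_PLASTIC_SMALL_SILO_KG * math.ceil(
            mass_t / SMALL_SILO_CAPACITY_T
        ) if mass_t > 0 else 0.0
    else:
        raise ValueError(f"unknown silage method {method!r}")
    try:
        loss = SILAGE_DM_LOSS[crop]
    except KeyError:
        raise ValueError(f"unknown silage crop {crop!r}; use 'cereal' or 'maize'")
    dm_lost_kg = mass_t * 1000.0 * dm_fraction * loss
    return {
        "plastic_co2": plastic_kg * CO2_PLASTIC_KG,
        "fermentation_co2": dm_lost_kg * SILAGE_CO2_PER_KG_DM_LOST,
    }


def carbon_sequestration(
    residue_dm_kg: float,
    manure_n_kg: float = 0.0,
    humification: float = HUMIFICATION_DEFAULT,
) -> float:
    """CO2 sequestered (kg, positive = removal) from plant residues (45% C)
    and applied manure (C = 13.4 x manure N), at the humification fraction
    of incorporated carbon retained in soil organic matter."""
    if not 0 <= humification <= 1:
        raise ValueError("humification must be in [0, 1]")
    if residue_dm_kg < 0 or manure_n_kg < 0:
        raise ValueError("inputs must be non-negative")
    carbon = PLANT_C_FRACTION * residue_dm_kg + MANURE_C_PER_N * manure_n_kg
    return humification * carbon * 44.0 / 12.0
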