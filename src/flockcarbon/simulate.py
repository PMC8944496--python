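"""Whole-farm simulation: from a validated farm-year to an emission ledger,
nutrient balances and the multi-footprint report.

The pipeline is deterministic: herd and land structure fix the diet, the
diet fixes enteric methane and excreta, excreta and purchases fix the
nitrogen cascades and embedded emissions, and the ledger plus the product
flows fix every footprint.  All coefficients come from the factor modules
(:mod:`flockcarbon.emissions`, :mod:`flockcarbon.manure`,
:mod:`flockcarbon.assessment`) and can be monkey-patched or overridden
through the CSV loaders in :mod:`flockcarbon.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import assessment, emissions, empirical, manure, nutrition
from .emissions import EmissionLedger, Gas
from .farm import FarmConfig, ForageUse, livestock_units, validate_farm
from .manure import ManureBudget, NutrientBalance

# Fixture feed compositions (DM basis). A small shipped table standing in
# for the regional feed-composition databases.
FEEDS = {
    "own_forage": nutrition.Feedstuff(
        "own_forage", dm_fraction=0.88, crude_protein=0.10, ndf=0.55,
        adf=0.33, omd=0.62, ne_mcal_per_kg=1.25, p_fraction=0.0025),
    "purchased_forage": nutrition.Feedstuff(
        "purchased_forage", dm_fraction=0.88, crude_protein=0.12, ndf=0.50,
        adf=0.32, omd=0.64, ne_mcal_per_kg=1.30, p_fraction=0.0025),
    "concentrate": nutrition.Feedstuff(
        "concentrate", dm_fraction=0.89, crude_protein=0.18, ndf=0.22,
        adf=0.10, omd=0.80, starch=0.40, ne_mcal_per_kg=1.80,
        p_fraction=0.0045),
    "concentrate_fibrous": nutrition.Feedstuff(
        "concentrate_fibrous", dm_fraction=0.89, crude_protein=0.16,
        ndf=0.38, adf=0.22, omd=0.70, starch=0.18, ne_mcal_per_kg=1.55,
        p_fraction=0.0050),
    "soybean": nutrition.Feedstuff(
        "soybean", dm_fraction=0.88, crude_protein=0.44, ndf=0.14,
        adf=0.08, omd=0.88, ne_mcal_per_kg=2.05, p_fraction=0.0062),
    "peas": nutrition.Feedstuff(
        "peas", dm_fraction=0.88, crude_protein=0.23, ndf=0.16, adf=0.08,
        omd=0.85, starch=0.45, ne_mcal_per_kg=1.95, p_fraction=0.0042),
    "pasture": nutrition.Feedstuff(
        "pasture", dm_fraction=0.25, crude_protein=0.14, ndf=0.48,
        adf=0.28, omd=0.68, ne_mcal_per_kg=1.40, p_fraction=0.0030),
}

FORAGE_UTILIZATION = 0.85  # share of on-farm forage production actually fed
REPLACEMENT_DMI_RATIO = 0.45  # replacement DMI relative to an adult
REPLACEMENT_AGE_DAYS = 240.0


@dataclass
class FarmResult:
    """Everything one simulation produces."""

    farm: FarmConfig
    lu: float
    ledger: EmissionLedger
    manure: ManureBudget
    balances: dict[str, NutrientBalance]
    report: assessment.FootprintReport
    diet: dict[str, float]
    intermediates: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def co2e_total(self) -> float:
        return emissions.co2e(self.ledger)


def build_diet(farm: FarmConfig, concentrate_feed: str = "concentrate",
               soybean_feed: str = "soybean") -> nutrition.Ration:
    """Average adult ration (kg DM/head/day) from on-farm forage production
    and purchased feeds, spread over the adult herd plus replacement
    animals at their intake ratio."""
    adult_eq = farm.herd.adults + farm.herd.replacements * REPLACEMENT_DMI_RATIO
    if adult_eq <= 0:
        raise ValueError("farm has no animals")
    own_forage_kg_dm = sum(
        p.production_kg_dm for p in farm.land
        if p.use.value in ("hay", "silage_bag", "silage_round_bale", "grazing")
    ) * FORAGE_UTILIZATION
    per_head_day = 1.0 / (adult_eq * 365.0)
    comps = []
    if own_forage_kg_dm > 0:
        comps.append((FEEDS["own_forage"], own_forage_kg_dm * per_head_day))
    p = farm.purchases
    if p.forage_kg > 0:
        f = FEEDS["purchased_forage"]
        comps.append((f, p.forage_kg * f.dm_fraction * per_head_day))
    if p.concentrate_kg > 0:
        f = FEEDS[concentrate_feed]
        comps.append((f, p.concentrate_kg * f.dm_fraction * per_head_day))
    if p.soybean_kg > 0:
        f = FEEDS[soybean_feed]
        comps.append((f, p.soybean_kg * f.dm_fraction * per_head_day))
    grazed_area = farm.communal_pasture_ha + sum(
        p.area_ha for p in farm.land if p.use is ForageUse.GRAZING)
    if farm.grazing_time_fraction > 0 and grazed_area > 0:
        # grazing substitutes conserved feed at equal DM intake: the
        # pasture share of the diet equals the grazing time fraction
        # (capped at 50%), scaling the conserved components down
        share = min(0.5, farm.grazing_time_fraction)
        comps = [(f, kg * (1.0 - share)) for f, kg in comps]
        base_dm = sum(kg for _, kg in comps)
        graze_dm = base_dm * share / (1.0 - share)
        comps.append((FEEDS["pasture"], graze_dm))
    if not comps:
        raise ValueError("farm has no feed supply")
    return nutrition.Ration(components=comps, animal_class="adult")


def simulate(farm: FarmConfig, concentrate_feed: str = "concentrate",
             soybean_feed: str = "soybean",
             humification: float = emissions.HUMIFICATION_DEFAULT,
             forage_omd_override: float | None = None) -> FarmResult:
    """Run the full pipeline on one farm-year and return the result.

    ``concentrate_feed``/``soybean_feed`` select fixture compositions for
    scenario substitution; ``forage_omd_override`` replaces the own-forage
    digestibility (forage-quality scenarios).
    """
    problems = validate_farm(farm)
    lu = livestock_units(farm.herd)
    herd = farm.herd
    area = farm.total_ha

    ration = build_diet(farm, concentrate_feed, soybean_feed)
    if forage_omd_override is not None:
        comps = [
            (nutrition.Feedstuff(**{**vars(f), "omd": forage_omd_override}), kg)
            if f.name in ("own_forage", "purchased_forage") else (f, kg)
            for f, kg in ration.components
        ]
        ration = nutrition.Ration(components=comps, animal_class="adult")
    diet = nutrition.ration_totals(ration)

    # --- enteric methane -------------------------------------------------
    omd_pct = diet["omd_weighted"] * 100.0
    ym_pct = emissions.ym(omd_pct)
    adult_eq = herd.adults + herd.replacements * REPLACEMENT_DMI_RATIO
    ch4_g_head_day = emissions.enteric_ch4(diet["dmi_g"], ym_pct)
    enteric_ch4_kg = ch4_g_head_day * adult_eq * 365.0 / 1000.0

    # --- excreta and manure ----------------------------------------------
    adult_ex = empirical.excreta_predict(
        omd=diet["omd_weighted"], dmi_g=diet["dmi_g"], gp_g=diet["gp_g"],
        ndf_g=diet["ndf_g"], n_intake_g=diet["n_g"], cap_n=True,
    )
    species = farm.breed_group.species
    gomp = (empirical.GOMPERTZ_GOAT if species == "goat"
            else empirical.GOMPERTZ_SHEEP)
    repl_lw = empirical.gompertz_weight(gomp, REPLACEMENT_AGE_DAYS)
    repl_n_intake_g = diet["n_g"] * REPLACEMENT_DMI_RATIO
    repl_ex = empirical.excreta_replacement(
        repl_n_intake_g / repl_lw**0.75
    )
    repl_n_g_day = (repl_ex["n_feces_g"] + repl_ex["n_urine_g"]) * repl_lw**0.75

    feces_kg_dm = adult_ex["feces_g_dm"] * adult_eq * 365.0 / 1000.0
    urine_L = adult_ex["urine_ml"] * adult_eq * 365.0 / 1000.0
    n_excreted_kg = (
        (adult_ex["n_feces_g"] + adult_ex["n_urine_g"]) * herd.adults
        + repl_n_g_day * herd.replacements
    ) * 365.0 / 1000.0

    bedding_kg = farm.bedding_straw_kg_per_female * herd.present_females
    budget = manure.manure_budget(
        feces_kg_dm=feces_kg_dm, urine_L=urine_L,
        n_excreted_kg=n_excreted_kg, bedding_kg=bedding_kg,
        grazing_share=farm.grazing_time_fraction,
        sold_kg=farm.manure_sold_kg,
    )

    ledger = EmissionLedger()
    ledger.add("enteric", Gas.CH4, enteric_ch4_kg)
    housed_manure_dm = budget.housed_kg * 0.35
    ledger.add("manure_mgmt", Gas.CH4, emissions.manure_ch4(housed_manure_dm))

    gas = emissions.nh3_n2o_animal(budget.n_housed_kg, budget.n_pasture_kg)
    ledger.add("housing", Gas.N2O, gas["n2o_housing"])
    ledger.add("grazing", Gas.N2O, gas["n2o_grazing"])
    nh3_total = gas["nh3_housing"] + gas["nh3_grazing"]

    # --- soil cascade ----------------------------------------------------
    sold_n = farm.manure_sold_kg * manure.GRAZING_N_FRAC
    applied_manure_n = max(
        0.0, budget.n_housed_kg - gas["nh3_housing"] * emissions.NH3_TO_N - sold_n
    )
    fert_n = farm.purchases.fertilizer_n_kg
    # crop residue N: straw/stubble at the cereal default, with a generic
    # 0.6% N content
    residue_dm = _residue_dm_kg(farm)
    residue_n = residue_dm * 0.006
    drain = emissions.drainage_mm(farm.climate) if farm.climate else 0.0
    applied_n_total = applied_manure_n + fert_n + budget.n_pasture_kg
    leached_n = emissions.leached_no3(applied_n_total, drain)
    purchased_forage_n = farm.purchases.forage_kg * FEEDS[
        "purchased_forage"].n_fraction
    purchased_conc_n = (
        farm.purchases.concentrate_kg * FEEDS[concentrate_feed].n_fraction
        + farm.purchases.soybean_kg * FEEDS[soybean_feed].n_fraction
    )
    n2o = emissions.soil_n2o(
        applied_manure_n_kg=applied_manure_n,
        fert_n_kg=fert_n,
        residue_n_kg=residue_n,
        volatilized_n_kg=nh3_total * emissions.NH3_TO_N,
        leached_n_kg=leached_n,
        purchased_forage_n_kg=purchased_forage_n,
        purchased_conc_n_kg=purchased_conc_n,
        purchased_fert_n_kg=fert_n,
    )
    ledger.add("soil_direct", Gas.N2O,
               n2o["soil_manure"] + n2o["soil_fertilizer"] + n2o["soil_residue"])
    ledger.add("soil_indirect_volatilization", Gas.N2O,
               n2o["indirect_volatilization"])
    ledger.add("soil_indirect_leaching", Gas.N2O, n2o["indirect_leaching"])
    ledger.add("purchased_inputs_n2o", Gas.N2O,
               n2o["purchased_forage"] + n2o["purchased_concentrate"])
    ledger.add("fertilizer_manufacture_n2o", Gas.N2O,
               n2o["fertilizer_manufacture"])

    # --- embedded CO2, silage, sequestration, add-ons --------------------
    embedded = emissions.embedded_co2(
        farm.purchases, lu=lu, lactating_females=herd.lactating,
        milking_time_min=farm.milking_time_min,
    )
    for item, kg in embedded.items():
        if kg:
            ledger.add(f"purchased_{item}", Gas.CO2, kg)

    silage_total = {"plastic_co2": 0.0, "fermentation_co2": 0.0}
    for p in farm.land:
        if p.use.value.startswith("silage") and p.production_kg_dm > 0:
            method = "bag" if p.use.value == "silage_bag" else "round_bale"
            crop = "maize" if p.crop.value == "maize_silage" else "cereal"
            fresh_t = p.production_kg_dm / 0.35 / 1000.0
            s = emissions.silage_co2(fresh_t, method, crop)
            silage_total["plastic_co2"] += s["plastic_co2"]
            silage_total["fermentation_co2"] += s["fermentation_co2"]
    if silage_total["plastic_co2"] or silage_total["fermentation_co2"]:
        ledger.add("silage", Gas.CO2,
                   silage_total["plastic_co2"] + silage_total["fermentation_co2"])

    cs_kg = emissions.carbon_sequestration(
        residue_dm_kg=residue_dm, manure_n_kg=applied_manure_n,
        humification=humification,
    )
    ledger.add("sequestration", Gas.CO2, -cs_kg)

    # land-use-change and soybean add-ons
    off_farm_feed = {
        "forage": farm.purchases.forage_kg,
        "concentrate": farm.purchases.concentrate_kg,
        "soybean": farm.purchases.soybean_kg,
    }
    fpcm_L = assessment.fpcm(farm.milk_total_L, farm.milk_fat_pct,
                             farm.milk_protein_pct)
    lu_result = assessment.land_use(
        off_farm_feed, on_farm_area_m2=farm.arable_ha * 10000.0,
        fpcm_L=max(fpcm_L, 1e-9),
    )
    iluc_kg = lu_result["off_m2"] * emissions.ILUC_CO2_KG_M2
    sy_kg = farm.purchases.soybean_kg * emissions.CO2_SOYBEAN_KG
    ledger.add("iLUC", Gas.CO2, iluc_kg)
    ledger.add("soybean", Gas.CO2, sy_kg)

    # --- footprints -------------------------------------------------------
    pcf = sum(
        e.co2e for e in ledger.entries
        if e.category not in ("iLUC", "soybean", "sequestration")
    )
    milk_kg = farm.milk_sold_L * manure.MILK_DENSITY_KG_L
    report = assessment.carbon_footprint_report(
        pcf=pcf, sy=sy_kg, iluc=iluc_kg, cs=cs_kg,
        area_ha=area, lu=lu, present_females=herd.present_females,
        fpcm_L=fpcm_L,
        meat_kg_ha=farm.live_weight_sold_kg / area if area else 0.0,
        milk_kg_ha=max(milk_kg / area if area else 0.0, 1e-9),
    )

    pot = assessment.impact_potentials(
        nh3_kg=nh3_total,
        no3_kg=leached_n * 62.0 / 14.0,  # NO3-N -> NO3 mass
    )
    report.ap_kg_so2e = pot["ap_kg_so2e"]
    report.ep_kg_no3e = pot["ep_kg_no3e"]

    crop_water_m3 = sum(
        p.area_ha * sum(m.etc_mm for m in farm.climate) * 10.0
        for p in farm.land if p.crop.value != "fallow"
    ) if farm.climate else 0.0
    wf = assessment.water_footprint(
        crop_water_m3=crop_water_m3,
        imported_kg={k: v for k, v in off_farm_feed.items() if k != "soybean"}
        | {"soybean": farm.purchases.soybean_kg},
        milk_L=farm.milk_sold_L,
        heads=herd.adults + herd.replacements,
        species=species,
    )
    report.wf_green, report.wf_blue, report.wf_grey = (
        wf["green"], wf["blue"], wf["grey"])
    report.wf_drinking, report.wf_cleaning = wf["drinking"], wf["cleaning"]

    diesel_L = (farm.purchases.diesel_L if farm.purchases.diesel_L > 0
                else emissions.DIESEL_L_PER_LU * lu)
    kwh = farm.purchases.electricity_kwh or (
        emissions.ELECTRICITY_KWH_PER_EWE_MIN * herd.lactating
        * farm.milking_time_min
    )
    ef = assessment.energy_footprint(
        diesel_L, kwh,
        {
            "fertilizer_n_kg": fert_n,
            "fertilizer_p2o5_kg": farm.purchases.fertilizer_p2o5_kg,
            "fertilizer_k2o_kg": farm.purchases.fertilizer_k2o_kg,
            "concentrate_kg": farm.purchases.concentrate_kg,
            "forage_kg": farm.purchases.forage_kg,
            "soybean_kg": farm.purchases.soybean_kg,
            "plastic_kg": farm.purchases.plastic_kg,
            "milk_replacer_kg": farm.purchases.milk_replacer_kg,
        },
    )
    report.ef_direct_mj, report.ef_indirect_mj = ef["direct_mj"], ef["indirect_mj"]

    balances = manure.farm_n_p_balance(farm)
    nft = (purchased_forage_n + purchased_conc_n + fert_n
           + farm.purchases.animals_liveweight_kg * manure.ANIMAL_N_PER_KG_LW
           + manure.ATMOSPHERIC_N_KG_HA * area
           + sum(manure.LEGUME_FIXATION_KG_N_HA.get(p.crop.value, 0.0)
                 * p.area_ha for p in farm.land))
    n2o_n_total = sum(
        e.kg for e in ledger.entries if e.gas is Gas.N2O) / emissions.N2O_N_TO_N2O
    nfr = nh3_total * emissions.NH3_TO_N + n2o_n_total + leached_n
    report.nf_total_kg_n = nft
    report.nf_reactive_kg_n = nfr
    report.land_use_on_m2_L = lu_result["on_m2_per_L"]
    report.land_use_off_m2_L = lu_result["off_m2_per_L"]

    return FarmResult(
        farm=farm, lu=lu, ledger=ledger, manure=budget, balances=balances,
        report=report, diet=diet,
        intermediates={
            "ym_pct": ym_pct,
            "enteric_ch4_kg": enteric_ch4_kg,
            "nh3_kg": nh3_total,
            "leached_n_kg": leached_n,
            "applied_manure_n_kg": applied_manure_n,
            "residue_dm_kg": residue_dm,
            "drainage_mm": drain,
            "diesel_L": diesel_L,
            "electricity_kwh": kwh,
            "fpcm_L": fpcm_L,
            "cs_kg": cs_kg,
            "sy_kg": sy_kg,
            "iluc_kg": iluc_kg,
        },
        warnings=problems,
    )


def _residue_dm_kg(farm: FarmConfig) -> float:
    """Crop residues returned to soil: cereal straw/stubble at the regional
    default per hectare, maize at 19% and alfalfa at 34% of harvest."""
    total = 0.0
    for p in farm.land:
        crop = p.crop.value
        if crop in ("barley_grain", "oats_forage", "triticale_forage",
                    "vetch_oat"):
            total += emissions.CEREAL_STRAW_KG_DM_HA * p.area_ha
        elif crop == "maize_silage":
            total += emissions.MAIZE_RESIDUE_SHARE * p.production_kg_dm
        elif crop == "alfalfa":
            total += emissions.ALFALFA_RESIDUE_SHARE * p.production_kg_dm
    return total
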