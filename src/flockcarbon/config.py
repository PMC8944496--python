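"""Configuration I/O: farm descriptions in YAML, coefficient tables in CSV,
report serialization to CSV/JSON.

Schema violations are reported with field paths (pydantic validation), and
every factor table the simulation uses can be dumped for auditing.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from pydantic import ValidationError

from . import assessment, emissions, empirical, manure
from .farm import DEFAULT_LU_TABLE, FarmConfig


class ConfigError(ValueError):
    """A farm or coefficient file failed validation; message carries paths."""


def load_farm(path: str | Path) -> FarmConfig:
    """Load and validate a farm-year from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"farm config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return FarmConfig.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"  {'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in err.errors()
        ]
        raise ConfigError(
            f"invalid farm config {path}:\n" + "\n".join(lines)
        ) from err


def dump_farm(farm: FarmConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(farm.model_dump_json()), fh, sort_keys=False)


def load_lu_table(path: str | Path | None = None) -> dict[str, float]:
    """Livestock-unit coefficients from a CSV with columns class,coefficient;
    defaults to the packaged table."""
    if path is None:
        with resources.files("flockcarbon.data").joinpath(
            "lu_coefficients.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = {"class", "coefficient"} - set(df.columns)
    if missing:
        raise ConfigError(f"LU table missing columns: {sorted(missing)}")
    return dict(zip(df["class"], df["coefficient"].astype(float)))


def load_model_specs(path: str | Path | None = None
                     ) -> dict[str, empirical.LinearModelSpec]:
    """Regression sub-models from a CSV (model,term,beta,se,n,r2); the
    'intercept' term row carries the constant.  Defaults to the packaged
    catalogue, which matches the in-code models."""
    if path is None:
        with resources.files("flockcarbon.data").joinpath(
            "model_coefficients.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    specs = {}
    for name, grp in df.groupby("model"):
        inter = grp[grp["term"] == "intercept"]
        if inter.empty:
            raise ConfigError(f"model {name!r} has no intercept row")
        coefs = {
            r["term"]: float(r["beta"])
            for _, r in grp.iterrows() if r["term"] != "intercept"
        }
        specs[name] = empirical.LinearModelSpec(
            name=name,
            intercept=float(inter["beta"].iloc[0]),
            coefficients=coefs,
            residual_se=float(inter["se"].iloc[0]),
            n=int(inter["n"].iloc[0]),
            r2=float(inter["r2"].iloc[0]),
        )
    return specs


def active_factors() -> pd.DataFrame:
    """Every emission/assessment factor currently in force, one row each."""
    rows = []

    def add(module: str, name: str, value, units: str = "") -> None:
        rows.append({"module": module, "factor": name, "value": value,
                     "units": units})

    em = emissions
    add("emissions", "GWP_CH4", em.GWP["CH4"], "kg CO2e/kg")
    add("emissions", "GWP_N2O", em.GWP["N2O"], "kg CO2e/kg")
    add("emissions", "GE_MJ_PER_KG", em.GE_MJ_PER_KG, "MJ/kg DM")
    add("emissions", "CH4_ENERGY_MJ_PER_KG", em.CH4_ENERGY_MJ_PER_KG, "MJ/kg")
    add("emissions", "NH3_EF_HOUSED", em.NH3_EF_HOUSED, "kg NH3/kg N")
    add("emissions", "NH3_EF_GRAZING", em.NH3_EF_GRAZING, "kg NH3/kg N")
    add("emissions", "N2O_PER_NH3_HOUSED", em.N2O_PER_NH3_HOUSED, "kg N2O/kg NH3")
    add("emissions", "N2O_GRAZING", em.N2O_GRAZING, "kg N2O/kg N")
    add("emissions", "EF_SOIL_MANURE", em.EF_SOIL_MANURE, "kg N2O-N/kg N")
    add("emissions", "EF_SOIL_FERT", em.EF_SOIL_FERT, "kg N2O-N/kg N")
    add("emissions", "EF_SOIL_RESIDUE", em.EF_SOIL_RESIDUE, "kg N2O-N/kg N")
    add("emissions", "EF_VOLATILIZED", em.EF_VOLATILIZED, "kg N2O-N/kg N")
    add("emissions", "EF_LEACHED", em.EF_LEACHED, "kg N2O-N/kg N")
    add("emissions", "CO2_DIESEL_L", em.CO2_DIESEL_L, "kg CO2/L")
    add("emissions", "CO2_ELECTRICITY_KWH", em.CO2_ELECTRICITY_KWH, "kg CO2/kWh")
    add("emissions", "CO2_FERT_N", em.CO2_FERT_N, "kg CO2/kg N")
    add("emissions", "CO2_SOYBEAN_KG", em.CO2_SOYBEAN_KG, "kg CO2/kg")
    add("emissions", "ILUC_CO2_KG_M2", em.ILUC_CO2_KG_M2, "kg CO2/m2")
    add("emissions", "DIESEL_L_PER_LU", em.DIESEL_L_PER_LU, "L/LU/yr")
    add("manure", "GRAZING_N_FRAC", manure.GRAZING_N_FRAC, "kg N/kg")
    add("manure", "GRAZING_P_FRAC", manure.GRAZING_P_FRAC, "kg P/kg")
    add("manure", "GRAZING_K_FRAC", manure.GRAZING_K_FRAC, "kg K/kg")
    add("manure", "ATMOSPHERIC_N_KG_HA", manure.ATMOSPHERIC_N_KG_HA, "kg N/ha/yr")
    add("assessment", "ALLOCATION_SLOPE", assessment.ALLOCATION_SLOPE, "")
    add("assessment", "AP_NH3", assessment.AP_NH3, "kg SO2e/kg")
    add("assessment", "EP_NH3", assessment.EP_NH3, "kg NO3e/kg")
    add("assessment", "EP_PO4", assessment.EP_PO4, "kg NO3e/kg")
    add("assessment", "CLEANING_WATER_L_PER_L_MILK",
        assessment.CLEANING_WATER_L_PER_L_MILK, "L/L milk")
    for cls, coef in DEFAULT_LU_TABLE.items():
        add("farm", f"LU_{cls}", coef, "LU/head")
    return pd.DataFrame(rows)


def ledger_to_frame(ledger) -> pd.DataFrame:
    return pd.DataFrame([
        {"category": e.category, "gas": e.gas.value, "kg": e.kg,
         "kg_co2e": e.co2e}
        for e in ledger.entries
    ])


def report_to_dict(result) -> dict:
    """Flatten a FarmResult into a JSON-serializable report."""
    rep = result.report
    return {
        "lu": result.lu,
        "pcf_kg_co2e": rep.pcf_kg_co2e,
        "tcf_kg_co2e": rep.tcf_kg_co2e,
        "sy_kg_co2e": rep.sy_kg_co2e,
        "iluc_kg_co2e": rep.iluc_kg_co2e,
        "cs_kg_co2e": rep.cs_kg_co2e,
        "allocation_factor": rep.af,
        "meat_milk_ratio": rep.r,
        "fpcm_L": rep.fpcm_L,
        "per_fu": rep.per_fu,
        "ap_kg_so2e": rep.ap_kg_so2e,
        "ep_kg_no3e": rep.ep_kg_no3e,
        "wf_total_m3": rep.wf_total_m3,
        "wf_partial_m3": rep.wf_partial_m3,
        "ef_total_mj": rep.ef_total_mj,
        "nf_total_kg_n": rep.nf_total_kg_n,
        "nf_reactive_kg_n": rep.nf_reactive_kg_n,
        "land_use_total_m2_L": rep.land_use_total_m2_L,
        "n_balance": {
            "inputs_kg_ha": result.balances["N"].inputs_kg_ha,
            "outputs_kg_ha": result.balances["N"].outputs_kg_ha,
            "surplus_kg_ha": result.balances["N"].surplus_kg_ha,
            "efficiency_pct": result.balances["N"].efficiency_pct,
        },
        "p_balance": {
            "inputs_kg_ha": result.balances["P"].inputs_kg_ha,
            "outputs_kg_ha": result.balances["P"].outputs_kg_ha,
            "surplus_kg_ha": result.balances["P"].surplus_kg_ha,
            "efficiency_pct": result.balances["P"].efficiency_pct,
        },
        "warnings": result.warnings,
    }
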