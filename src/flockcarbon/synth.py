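"""Seeded generators for farms, metabolic-trial records, forage trials and
monthly climate, emulating the survey's printed statistical structure.

Farm fields are drawn from truncated normals (rejecting negatives) at the
per-breed-group survey means and standard deviations; metabolic and forage
trial responses are the published regression models plus Gaussian noise at
the published residual standard errors.  Every generator is a pure
function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from . import empirical
from .farm import (
    BreedGroup, ClimateMonth, Crop, FarmConfig, ForageUse, HerdInventory,
    LandParcel, PurchaseLedger,
)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  size: int | None = None, low: float = 0.0):
    """Left-truncated normal whose *realized* mean equals ``mean``.

    Survey tables print the moments of non-negative (often skewed) data;
    naive rejection below ``low`` would inflate the mean by up to half a
    standard deviation when sd is of the order of the mean.  The location
    parameter is therefore shifted so the truncated distribution's mean
    matches the printed mean; sampling uses the inverse CDF driven by the
    caller's generator, keeping determinism per seed.
    """
    from scipy import special

    if sd <= 0:
        return mean if size is None else np.full(size, float(mean))
    if mean <= low:
        raise ValueError(f"target mean {mean} must exceed truncation {low}")
    mu = _solve_location((mean - low) / sd) * sd + low
    alpha = (low - mu) / sd
    p_low = special.ndtr(alpha)
    u = rng.uniform(p_low, 1.0, size=1 if size is None else size)
    x = mu + sd * special.ndtri(u)
    x = np.maximum(x, low)  # guard against FP round-off at the boundary
    return float(x[0]) if size is None else x


@lru_cache(maxsize=256)
def _solve_location(target: float) -> float:
    """Standardized location m such that a unit-variance normal truncated
    below 0 with location m has mean ``target`` (> 0): the closed-form
    truncated mean is m + phi(m)/Phi(m) (hazard of the lower tail)."""
    from scipy import optimize, special

    def trunc_mean(m: float) -> float:
        # E[X | X > 0], X ~ N(m, 1): m + phi(m)/Phi(m), with the hazard
        # computed through erfcx for numerical stability at negative m
        hazard = np.sqrt(2.0 / np.pi) / special.erfcx(-m / np.sqrt(2.0))
        return m + float(hazard)

    return float(optimize.brentq(
        lambda m: trunc_mean(m) - target, -40.0, target, xtol=1e-10))


@dataclass(frozen=True)
class _GroupStats:
    """Survey means (sd) per breed group used by gen_farm."""

    total_ha: tuple[float, float]
    arable_ha: tuple[float, float]
    communal_ha: tuple[float, float]
    animals: tuple[float, float]
    lactating: tuple[float, float]
    replacement: tuple[float, float]
    purchased_forage_per_pf: tuple[float, float]   # kg DM/PF/yr
    purchased_conc_per_pf: tuple[float, float]
    grazing_time_pct: tuple[float, float]
    milk_per_pf: tuple[float, float]               # L FPCM/PF/yr
    fert_n_kg_ha: tuple[float, float]
    fert_p_kg_ha: tuple[float, float]
    fert_k_kg_ha: tuple[float, float]


GROUP_STATS: dict[BreedGroup, _GroupStats] = {
    BreedGroup.MANCHEGA: _GroupStats(
        total_ha=(1013, 814), arable_ha=(164, 168), communal_ha=(849, 843),
        animals=(1466, 980), lactating=(838, 558), replacement=(414, 326),
        purchased_forage_per_pf=(236, 119), purchased_conc_per_pf=(304, 44),
        grazing_time_pct=(27.9, 14.1), milk_per_pf=(307, 76),
        fert_n_kg_ha=(24.6, 37.2),
        fert_p_kg_ha=(7.6, 25.7), fert_k_kg_ha=(5.2, 14.9),
    ),
    BreedGroup.FOREIGNERS: _GroupStats(
        total_ha=(157, 215), arable_ha=(78, 88), communal_ha=(79, 159),
        animals=(1446, 1162), lactating=(1199, 950), replacement=(489, 470),
        purchased_forage_per_pf=(338, 90), purchased_conc_per_pf=(586, 143),
        grazing_time_pct=(3.7, 7.1), milk_per_pf=(479, 94),
        fert_n_kg_ha=(27.7, 42.7),
        fert_p_kg_ha=(7.7, 11.8), fert_k_kg_ha=(7.6, 11.8),
    ),
    BreedGroup.FLORIDA: _GroupStats(
        total_ha=(218, 339), arable_ha=(9, 7), communal_ha=(209, 338),
        animals=(228, 85), lactating=(122, 42), replacement=(52, 29),
        purchased_forage_per_pf=(250, 148), purchased_conc_per_pf=(430, 59),
        grazing_time_pct=(16.5, 17.1), milk_per_pf=(381, 63),
        fert_n_kg_ha=(11.1, 17.5),
        fert_p_kg_ha=(0.13, 0.21), fert_k_kg_ha=(0.13, 0.21),
    ),
}

# Forage yields, t DM/ha (survey means); genetic index distribution is a
# stated assumption (the survey index itself is not published)
FORAGE_YIELD_T_HA = {"oats": 4.9, "triticale": 4.6, "barley": 2.9}
GENETIC_VALUE_MEAN = 8.0
GENETIC_VALUE_SD = 1.5


def gen_farm(seed: int, breed_group: BreedGroup | str = BreedGroup.MANCHEGA,
             climate_seed_offset: int = 101) -> FarmConfig:
    """One internally consistent synthetic farm-year for a breed group.

    Herd sub-classes are rescaled after sampling so lactating + dry animals
    equal the sampled census; milk, purchases and fertilizer scale with the
    sampled herd and land.  Deterministic per (seed, breed_group).
    """
    breed_group = BreedGroup(breed_group)
    stats = GROUP_STATS[breed_group]
    rng = np.random.default_rng(seed)

    arable = _trunc_normal(rng, *stats.arable_ha, low=1.0)
    communal = _trunc_normal(rng, *stats.communal_ha)
    animals = max(20.0, _trunc_normal(rng, *stats.animals, low=10.0))
    lactating = min(_trunc_normal(rng, *stats.lactating, low=5.0), 0.95 * animals)
    replacement = _trunc_normal(rng, *stats.replacement)
    present_females = animals
    non_lactating = max(0.0, present_females - lactating)
    # lactating batches split high/medium/low roughly as surveyed (46/29/25)
    lact_split = (0.46, 0.29, 0.25)
    demog = empirical.demography(present_females)
    offspring = demog.born_offspring

    herd = HerdInventory(
        present_females=present_females,
        lactating_high=lactating * lact_split[0],
        lactating_medium=lactating * lact_split[1],
        lactating_low=lactating * lact_split[2],
        non_lactating=non_lactating,
        replacement_0_4=replacement * 0.33,
        replacement_4_12=replacement * 0.67,
        studs=max(1.0, round(present_females / 40.0)),
        offspring=offspring,
        genetic_value=_trunc_normal(
            rng, GENETIC_VALUE_MEAN, GENETIC_VALUE_SD, low=1.0
        ),
    )

    grazing_frac = min(1.0, _trunc_normal(rng, *stats.grazing_time_pct) / 100.0)
    milk_per_pf = _trunc_normal(rng, *stats.milk_per_pf, low=50.0)
    milk_total = milk_per_pf * present_females
    milk_sold = max(0.0, milk_total - offspring * 35.0)

    fert_n = _trunc_normal(rng, *stats.fert_n_kg_ha)
    fert_p = _trunc_normal(rng, *stats.fert_p_kg_ha)
    fert_k = _trunc_normal(rng, *stats.fert_k_kg_ha)

    # land split: fallow 40.8%, grain 26.4%, forages 24.2%, maize 3.3%,
    # legumes 9.7% of arable (survey shares; maize/legumes zero-inflated
    # outside the Manchega group)
    shares = {"fallow": 0.408, "grain": 0.264, "forage": 0.242}
    is_m = breed_group is BreedGroup.MANCHEGA
    land = [
        LandParcel(crop=Crop.FALLOW, area_ha=arable * shares["fallow"]),
        LandParcel(crop=Crop.BARLEY_GRAIN, area_ha=arable * shares["grain"],
                   yield_t_dm_ha=FORAGE_YIELD_T_HA["barley"],
                   use=ForageUse.GRAIN, fert_n=fert_n, fert_p=fert_p,
                   fert_k=fert_k),
        LandParcel(crop=Crop.OATS_FORAGE, area_ha=arable * shares["forage"] / 2,
                   yield_t_dm_ha=FORAGE_YIELD_T_HA["oats"],
                   use=ForageUse.HAY, fert_n=fert_n, fert_p=fert_p,
                   fert_k=fert_k),
        LandParcel(crop=Crop.TRITICALE_FORAGE,
                   area_ha=arable * shares["forage"] / 2,
                   yield_t_dm_ha=FORAGE_YIELD_T_HA["triticale"],
                   use=ForageUse.SILAGE_BAG, fert_n=fert_n, fert_p=fert_p,
                   fert_k=fert_k),
    ]
    if is_m:
        land.append(LandParcel(crop=Crop.MAIZE_SILAGE, area_ha=arable * 0.033,
                               yield_t_dm_ha=15.7, use=ForageUse.SILAGE_BAG))
        land.append(LandParcel(crop=Crop.ALFALFA, area_ha=arable * 0.053,
                               yield_t_dm_ha=14.7, use=ForageUse.HAY))

    purchases = PurchaseLedger(
        forage_kg=_trunc_normal(rng, *stats.purchased_forage_per_pf)
        * present_females,
        concentrate_kg=_trunc_normal(rng, *stats.purchased_conc_per_pf)
        * present_females * 0.85,
        soybean_kg=_trunc_normal(rng, *stats.purchased_conc_per_pf)
        * present_females * 0.15,
        fertilizer_n_kg=fert_n * arable,
        fertilizer_p2o5_kg=fert_p / 0.4364 * arable,
        fertilizer_k2o_kg=fert_k / 0.8301 * arable,
        bedding_straw_kg=225.0 * present_females,
    )

    # meat stream from the demography model: culled offspring at the
    # suckling slaughter weight plus adult losses at mature weight
    species = breed_group.species
    gomp = (empirical.GOMPERTZ_GOAT if species == "goat"
            else empirical.GOMPERTZ_SHEEP)
    slaughter_w = empirical.gompertz_weight(gomp, 35.0)
    adult_w = empirical.gompertz_weight(gomp, 480.0)
    lw_sold = (demog.culled_offspring * slaughter_w
               + 0.2 * demog.adult_losses * adult_w)

    return FarmConfig(
        breed_group=breed_group,
        land=land,
        communal_pasture_ha=communal,
        herd=herd,
        purchases=purchases,
        grazing_time_fraction=grazing_frac,
        milking_time_min=_trunc_normal(rng, 120.0, 30.0, low=30.0),
        milk_sold_L=milk_sold,
        milk_fat_pct=_trunc_normal(rng, 6.5, 0.5, low=3.0),
        milk_protein_pct=_trunc_normal(rng, 5.8, 0.4, low=3.0),
        live_weight_sold_kg=lw_sold,
        climate=gen_climate(seed + climate_seed_offset),
    )


def gen_metabolic_trials(n: int, seed: int, noise_scale: float = 1.0
                         ) -> pd.DataFrame:
    """Metabolic-chamber records: predictors from truncated normals at the
    trial means/sd, responses from the published models plus Gaussian noise
    at ``noise_scale`` x the published residual SE."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    omd = np.clip(_trunc_normal(rng, 0.633, 0.10, size=n, low=0.3), None, 0.95)
    dmi = _trunc_normal(rng, 791.5, 186.0, size=n, low=100.0)
    gp = _trunc_normal(rng, 143.8, 60.6, size=n, low=20.0)
    ndf = _trunc_normal(rng, 386.7, 104.9, size=n, low=50.0)
    n_intake = _trunc_normal(rng, 20.9, 8.5, size=n, low=1.0)

    def model_plus_noise(spec, X, se):
        mean = spec.intercept + sum(
            beta * X[k] for k, beta in spec.coefficients.items()
        )
        return mean + rng.normal(0.0, se * noise_scale, size=n)

    feces = model_plus_noise(
        empirical.FECES_MODEL,
        {"omd_pct_over_100": omd, "dmi_g": dmi, "gp_g": gp, "ndf_g": ndf},
        empirical.FECES_MODEL.residual_se,
    )
    urine = model_plus_noise(
        empirical.URINE_MODEL, {"n_intake_g": n_intake},
        empirical.URINE_MODEL.residual_se,
    )
    n_feces = model_plus_noise(
        empirical.N_FECES_MODEL, {"n_intake_g": n_intake},
        empirical.N_FECES_MODEL.residual_se,
    )
    n_urine = model_plus_noise(
        empirical.N_URINE_MODEL, {"n_intake_g": n_intake},
        empirical.N_URINE_MODEL.residual_se,
    )
    return pd.DataFrame({
        "omd": omd, "dmi_g": dmi, "gp_g": gp, "ndf_g": ndf,
        "n_intake_g": n_intake, "feces_g": feces, "urine_ml": urine,
        "n_feces_g": n_feces, "n_urine_g": n_urine,
    })


FORAGE_TRIAL_STATS = {
    "triticale": {"height": (82.4, 18.22), "days_to_ear": (154.2, 36.5),
                  "n_basal": (23.8, 14.1)},
    "oats": {"height": (70.5, 28.0)},
}


def gen_forage_trials(n: int, seed: int, crop: str = "triticale",
                      noise_scale: float = 1.0) -> pd.DataFrame:
    """Forage-trial records for triticale or oats: agronomic predictors at
    the trial distributions, yield from the published model plus noise."""
    if n < 2:
        raise ValueError("need n >= 2")
    if crop not in FORAGE_TRIAL_STATS:
        raise ValueError(f"unknown crop {crop!r}")
    rng = np.random.default_rng(seed)
    stats = FORAGE_TRIAL_STATS[crop]
    height = _trunc_normal(rng, *stats["height"], size=n, low=10.0)
    if crop == "triticale":
        days = _trunc_normal(rng, *stats["days_to_ear"], size=n, low=60.0)
        n_basal = _trunc_normal(rng, *stats["n_basal"], size=n)
        spec = empirical.TRITICALE_MODEL
        mean = (spec.intercept + spec.coefficients["height_cm"] * height
                + spec.coefficients["days_to_ear"] * days
                + spec.coefficients["n_basal_kg_ha"] * n_basal)
        df = pd.DataFrame({"height": height, "days_to_ear": days,
                           "n_basal": n_basal})
    else:
        spec = empirical.OATS_MODEL
        mean = spec.intercept + spec.coefficients["height_cm"] * height
        df = pd.DataFrame({"height": height})
    df["yield_kg_dm_ha"] = mean + rng.normal(
        0.0, spec.residual_se * noise_scale, size=n
    )
    return df


# Continental-Mediterranean monthly template (Castilla-La Mancha-like):
# (t_max, t_min, rainfall_mm, etc_mm)
_CLIMATE_TEMPLATE = [
    (9.0, 0.0, 35, 15), (11.5, 0.5, 32, 25), (15.5, 3.0, 30, 50),
    (18.0, 5.5, 45, 75), (23.0, 9.0, 40, 110), (29.5, 14.0, 20, 150),
    (33.5, 17.0, 8, 180), (33.0, 17.0, 8, 160), (27.5, 13.5, 30, 105),
    (20.5, 8.5, 45, 60), (13.5, 3.5, 40, 25), (9.5, 1.0, 40, 15),
]


def gen_climate(seed: int, months: int = 12, delta_t: float = 0.0
                ) -> list[ClimateMonth]:
    """Monthly climate series: seasonal template plus noise; ``delta_t``
    shifts every month's temperatures by a constant offset."""
    if months < 1:
        raise ValueError("months must be >= 1")
    rng = np.random.default_rng(seed)
    series = []
    for i in range(months):
        tmax, tmin, rain, etc = _CLIMATE_TEMPLATE[i % 12]
        jitter = rng.normal(0.0, 1.0)
        tmax_i = tmax + jitter + rng.normal(0.0, 0.5) + delta_t
        tmin_i = tmin + jitter + delta_t
        series.append(ClimateMonth(
            t_max=max(tmax_i, tmin_i),
            t_min=min(tmax_i, tmin_i),
            rainfall_mm=max(0.0, rain * rng.lognormal(0.0, 0.3)),
            relative_humidity_pct=float(np.clip(rng.normal(60, 8), 20, 95)),
            etc_mm=max(0.0, etc * rng.normal(1.0, 0.05)),
        ))
    return series
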