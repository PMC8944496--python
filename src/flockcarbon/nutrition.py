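"""Intake aggregation, potential production and nutrient-use efficiencies.

A :class:`Ration` is a list of (feedstuff, kg DM/head/day) pairs; its
mass-weighted totals feed the excreta regressions and the enteric-methane
calculation.  Potential milk is the energy left after maintenance divided
by the energy concentration of milk; potential milk protein applies the
species assimilation rate of absorbed amino acids (58% sheep, 68% goat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Feedstuff:
    """Chemical/bromatological composition; fractions are of dry matter."""

    name: str
    dm_fraction: float = 0.88
    crude_protein: float = 0.12  # GP fraction of DM
    ndf: float = 0.45
    adf: float = 0.28
    omd: float = 0.65
    starch: float = 0.10
    ee: float = 0.025
    ne_mcal_per_kg: float = 1.4
    gross_energy_mj_per_kg: float = 18.55
    p_fraction: float = 0.0035

    def __post_init__(self) -> None:
        for f in ("dm_fraction", "crude_protein", "ndf", "adf", "omd",
                  "starch", "ee", "p_fraction"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ValueError(f"{self.name}: {f}={v} outside [0, 1]")
        if self.ne_mcal_per_kg < 0 or self.gross_energy_mj_per_kg < 0:
            raise ValueError(f"{self.name}: energies must be non-negative")

    @property
    def n_fraction(self) -> float:
        # crude protein = 6.25 x N
        return self.crude_protein / 6.25


@dataclass
class Ration:
    components: list[tuple[Feedstuff, float]] = field(default_factory=list)
    animal_class: str = "lactating"
    grazing_km_per_day: float = 0.0
    grazing_hours: float = 0.0

    def __post_init__(self) -> None:
        for feed, kg in self.components:
            if kg < 0:
                raise ValueError(f"negative amount for {feed.name}")


def ration_totals(r: Ration) -> dict[str, float]:
    """Per head-day totals: DM intake, N, crude protein, NDF, energy and P
    as mass-weighted sums; OMD as the DM-weighted mean."""
    if not r.components:
        raise ValueError("ration has no components")
    dmi_kg = sum(kg for _, kg in r.components)
    if dmi_kg == 0:
        raise ValueError("ration has zero total dry matter")
    totals = {
        "dmi_g": dmi_kg * 1000.0,
        "n_g": sum(kg * f.n_fraction for f, kg in r.components) * 1000.0,
        "gp_g": sum(kg * f.crude_protein for f, kg in r.components) * 1000.0,
        "ndf_g": sum(kg * f.ndf for f, kg in r.components) * 1000.0,
        "omd_weighted": sum(kg * f.omd for f, kg in r.components) / dmi_kg,
        "ge_mj": sum(kg * f.gross_energy_mj_per_kg for f, kg in r.components),
        "ne_mcal": sum(kg * f.ne_mcal_per_kg for f, kg in r.components),
        "p_g": sum(kg * f.p_fraction for f, kg in r.components) * 1000.0,
    }
    return totals


def potential_milk(
    nei_mcal: float, nem_mcal: float, energy_per_liter_mcal: float
) -> float:
    """Liters/day supported by net energy intake after maintenance
    (grazing activity included in ``nem_mcal`` by the caller)."""
    if energy_per_liter_mcal <= 0:
        raise ValueError("energy_per_liter_mcal must be positive")
    surplus = nei_mcal - nem_mcal
    if surplus < 0:
        warnings.warn(
            "net energy intake below maintenance; potential milk clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return surplus / energy_per_liter_mcal


ASSIMILATION_RATE = {"sheep": 0.58, "goat": 0.68}

# Lactation efficiency of metabolizable energy (k_L); config scalar
K_L_DEFAULT = 0.60

# Per-class requirement coefficients (literature defaults, overridable):
# maintenance NE Mcal/day per kg metabolic weight, and the energy cost of
# locomotion while grazing, Mcal per km travelled
REQUIREMENT_COEFFICIENTS = {
    "lactating": {"nem_mcal_per_kg075": 0.080, "walk_mcal_per_km": 0.012},
    "non_lactating": {"nem_mcal_per_kg075": 0.065, "walk_mcal_per_km": 0.012},
    "replacement": {"nem_mcal_per_kg075": 0.070, "walk_mcal_per_km": 0.010},
}


def maintenance_ne(
    live_weight_kg: float,
    animal_class: str = "lactating",
    grazing_km_per_day: float = 0.0,
    coefficients: dict[str, dict[str, float]] | None = None,
) -> float:
    """Maintenance net energy (Mcal/head/day) including grazing activity.

    NEm = a * LW^0.75 + b * km walked, with per-class coefficients a, b.
    """
    if live_weight_kg <= 0:
        raise ValueError("live_weight_kg must be positive")
    table = REQUIREMENT_COEFFICIENTS if coefficients is None else coefficients
    try:
        coef = table[animal_class]
    except KeyError:
        raise ValueError(
            f"no requirement coefficients for class {animal_class!r}")
    return (coef["nem_mcal_per_kg075"] * live_weight_kg**0.75
            + coef["walk_mcal_per_km"] * grazing_km_per_day)


def potential_milk_protein(
    mp_intake_g: float, species: str, maintenance_g: float = 0.0
) -> float:
    """Grams of milk protein/day from metabolizable protein intake after
    the maintenance deduction, at the species amino-acid assimilation rate."""
    if mp_intake_g < 0:
        raise ValueError("mp_intake_g must be non-negative")
    try:
        rate = ASSIMILATION_RATE[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; use 'sheep' or 'goat'")
    return max(0.0, mp_intake_g - maintenance_g) * rate


def nue_pue(
    n_milk: float, n_meat: float, n_intake: float,
    p_milk: float, p_meat: float, p_intake: float,
) -> dict[str, float]:
    """Nitrogen and phosphorus use efficiency: nutrient in milk + meat as a
    percentage of nutrient ingested.  Values above 100% indicate a broken
    mass balance and trigger a warning."""
    if n_intake <= 0 or p_intake <= 0:
        raise ValueError("nutrient intakes must be positive")
    nue = 100.0 * (n_milk + n_meat) / n_intake
    pue = 100.0 * (p_milk + p_meat) / p_intake
    if nue > 100 or pue > 100:
        warnings.warn(
            f"efficiency above 100% (NUE={nue:.1f}, PUE={pue:.1f}): "
            "outputs exceed intake",
            stacklevel=2,
        )
    return {"nue_pct": nue, "pue_pct": pue}
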