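import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from flockcarbon import (  # noqa: E402
    BreedGroup, ClimateMonth, Crop, FarmConfig, ForageUse, HerdInventory,
    LandParcel, PurchaseLedger,
)
from flockcarbon.synth import gen_climate, gen_farm


@pytest.fixture
def small_farm() -> FarmConfig:
    """A hand-built 100-ewe dairy sheep farm with round numbers."""
    herd = HerdInventory(
        present_females=100,
        lactating_high=30, lactating_medium=20, lactating_low=10,
        non_lactating=40,
        replacement_0_4=8, replacement_4_12=18,
        studs=3, offspring=80,
        genetic_value=8.0,
    )
    land = [
        LandParcel(crop=Crop.OATS_FORAGE, area_ha=10, yield_t_dm_ha=4.9,
                   use=ForageUse.HAY, fert_n=30, fert_p=8, fert_k=5),
        LandParcel(crop=Crop.TRITICALE_FORAGE, area_ha=8, yield_t_dm_ha=4.6,
                   use=ForageUse.SILAGE_BAG, fert_n=30, fert_p=8, fert_k=5),
        LandParcel(crop=Crop.BARLEY_GRAIN, area_ha=12, yield_t_dm_ha=2.9,
                   use=ForageUse.GRAIN, fert_n=40),
        LandParcel(crop=Crop.FALLOW, area_ha=10),
    ]
    purchases = PurchaseLedger(
        forage_kg=23000, concentrate_kg=30000, soybean_kg=4500,
        fertilizer_n_kg=1500, fertilizer_p2o5_kg=500, fertilizer_k2o_kg=300,
        bedding_straw_kg=22500,
    )
    return FarmConfig(
        breed_group=BreedGroup.MANCHEGA,
        land=land,
        communal_pasture_ha=60,
        herd=herd,
        purchases=purchases,
        grazing_time_fraction=0.25,
        milking_time_min=120,
        milk_sold_L=28000,
        milk_fat_pct=6.5,
        milk_protein_pct=5.8,
        live_weight_sold_kg=1500,
        climate=gen_climate(7),
    )


@pytest.fixture(scope="session")
def manchega_farm() -> FarmConfig:
    return gen_farm(11, BreedGroup.MANCHEGA)


@pytest.fixture(scope="session")
def florida_farm() -> FarmConfig:
    return gen_farm(12, BreedGroup.FLORIDA)
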