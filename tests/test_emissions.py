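import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockcarbon import (
    EmissionLedger, Gas, PurchaseLedger, carbon_sequestration, co2e,
    embedded_co2, enteric_ch4, leached_no3, manure_ch4, nh3_n2o_animal,
    silage_co2, soil_n2o, ym,
)


class TestYm:
    @pytest.mark.parametrize("omd,expect", [
        (65.0, 6.5), (63.3, 6.585), (100.0, 4.75)])
    def test_values(self, omd, expect):
        assert ym(omd) == pytest.approx(expect)

    def test_fractional_omd_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            ym(0.65)

    @given(st.floats(30, 99), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_omd(self, omd, d):
        if omd + d <= 100:
            assert ym(omd + d) < ym(omd)


class TestEntericCH4:
    def test_zero_intake(self):
        assert enteric_ch4(0, 6.5) == 0.0

    def test_kilogram_of_feed(self):
        assert enteric_ch4(1000, 6.5) == pytest.approx(21.67, abs=0.01)

    def test_linear_in_dmi(self):
        assert enteric_ch4(2000, 6.5) == pytest.approx(2 * enteric_ch4(1000, 6.5))


class TestManureCH4:
    def test_zero_mcf(self):
        assert manure_ch4(1000, mcf_fraction=0.0) == 0.0

    def test_chain_arithmetic(self):
        got = manure_ch4(1000, b0_m3_per_kg_vs=0.19, mcf_fraction=0.015,
                         vs_fraction=0.8)
        assert got == pytest.approx(1.53, abs=0.01)

    def test_monotone_in_each_factor(self):
        base = manure_ch4(1000)
        assert manure_ch4(2000) > base
        assert manure_ch4(1000, mcf_fraction=0.04) > base
        assert manure_ch4(1000, b0_m3_per_kg_vs=0.25) > base


class TestAmmoniaN2O:
    def test_housed_factors(self):
        out = nh3_n2o_animal(100, 0)
        assert out["nh3_housing"] == pytest.approx(10.0)
        assert out["n2o_housing"] == pytest.approx(0.015)

    def test_grazing_factors(self):
        out = nh3_n2o_animal(0, 100)
        assert out["nh3_grazing"] == pytest.approx(12.0)
        assert out["n2o_grazing"] == pytest.approx(2.2)

    def test_all_zero(self):
        assert all(v == 0 for v in nh3_n2o_animal(0, 0).values())

    @given(st.floats(0, 1e5), st.floats(0, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_nh3_never_exceeds_excreted_n(self, housed, grazing):
        out = nh3_n2o_animal(housed, grazing)
        assert out["nh3_housing"] + out["nh3_grazing"] <= housed + grazing


class TestSoilN2O:
    def test_fertilizer_direct_pathway(self):
        out = soil_n2o(fert_n_kg=1000)
        assert out["soil_fertilizer"] == pytest.approx(15.71, abs=0.01)

    def test_leaching_pathway(self):
        out = soil_n2o(leached_n_kg=100)
        assert out["indirect_leaching"] == pytest.approx(3.93, abs=0.01)

    def test_all_zero(self):
        assert all(v == 0 for v in soil_n2o().values())

    def test_n2o_n_never_exceeds_n_entering(self):
        out = soil_n2o(applied_manure_n_kg=100, fert_n_kg=100,
                       residue_n_kg=100, volatilized_n_kg=100,
                       leached_n_kg=100)
        for pathway, n2o_kg in out.items():
            assert n2o_kg * 28 / 44 <= 100 or pathway == "fertilizer_manufacture"


class TestLeaching:
    def test_no_drainage_no_leaching(self):
        assert leached_no3(100, 0) == 0.0

    def test_default_rule(self):
        assert leached_no3(100, 200) == pytest.approx(20.0)

    def test_monotone(self):
        assert leached_no3(100, 300) >= leached_no3(100, 200)
        assert leached_no3(200, 200) >= leached_no3(100, 200)

    def test_capped_fraction(self):
        assert leached_no3(100, 5000) == pytest.approx(30.0)


class TestEmbeddedCO2:
    def test_diesel(self):
        out = embedded_co2(PurchaseLedger(diesel_L=100))
        assert out["diesel"] == pytest.approx(331.0)

    def test_concentrate(self):
        out = embedded_co2(PurchaseLedger(concentrate_kg=1000))
        assert out["concentrate"] == pytest.approx(300.0)

    def test_diesel_default_from_livestock_units(self):
        out = embedded_co2(PurchaseLedger(), lu=10)
        assert out["diesel"] == pytest.approx(1224.7)

    def test_electricity_default_scales_with_milking(self):
        a = embedded_co2(PurchaseLedger(), lactating_females=100,
                         milking_time_min=120)
        b = embedded_co2(PurchaseLedger(), lactating_females=100,
                         milking_time_min=108)
        assert b["electricity"] == pytest.approx(0.9 * a["electricity"])


class TestSilage:
    def test_bag_silage_chain(self):
        out = silage_co2(10, "bag", "cereal")
        assert out["plastic_co2"] == pytest.approx(13.6)
        assert out["fermentation_co2"] == pytest.approx(103.3, abs=0.1)

    def test_zero_mass(self):
        out = silage_co2(0, "bag")
        assert out["plastic_co2"] == 0 and out["fermentation_co2"] == 0

    def test_maize_vs_cereal_loss_ratio(self):
        cereal = silage_co2(10, "bag", "cereal")["fermentation_co2"]
        maize = silage_co2(10, "bag", "maize")["fermentation_co2"]
        assert maize / cereal == pytest.approx(3.0 / 12.3)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            silage_co2(10, "tower")


class TestSequestration:
    def test_nothing_in_nothing_out(self):
        assert carbon_sequestration(0, 0) == 0.0

    def test_residue_chain(self):
        assert carbon_sequestration(1000, 0, humification=0.1) == pytest.approx(165.0)

    def test_linear_in_residue(self):
        assert carbon_sequestration(2000, 0) == pytest.approx(
            2 * carbon_sequestration(1000, 0))


class TestCO2e:
    def test_methane_weight(self):
        led = EmissionLedger()
        led.add("enteric", Gas.CH4, 1.0)
        assert co2e(led) == pytest.approx(28.0)

    def test_nitrous_oxide_weight(self):
        led = EmissionLedger()
        led.add("soil_direct", Gas.N2O, 1.0)
        assert co2e(led) == pytest.approx(298.0)

    def test_additive_over_concatenation(self):
        rng = np.random.default_rng(4)
        a, b = EmissionLedger(), EmissionLedger()
        for led in (a, b):
            for gas in Gas:
                led.add("x", gas, float(rng.uniform(0, 10)))
        both = EmissionLedger()
        both.extend(a)
        both.extend(b)
        assert co2e(both) == pytest.approx(co2e(a) + co2e(b))

    def test_sequestration_preserves_sign(self):
        led = EmissionLedger()
        led.add("sequestration", Gas.CO2, -100.0)
        led.add("enteric", Gas.CH4, 10.0)
        assert co2e(led) == pytest.approx(280.0 - 100.0)

    def test_negative_emission_rejected_outside_sequestration(self):
        led = EmissionLedger()
        with pytest.raises(ValueError):
            led.add("enteric", Gas.CH4, -1.0)

    def test_unknown_gas_rejected(self):
        led = EmissionLedger()
        with pytest.raises(ValueError):
            led.add("enteric", "CO", 1.0)
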