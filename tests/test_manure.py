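import pytest

from flockcarbon import farm_n_p_balance, manure_budget, soil_balance
from flockcarbon.manure import grazing_manure_nutrients, milk_n_kg


class TestManureBudget:
    def test_full_grazing_leaves_bedding_only(self):
        b = manure_budget(feces_kg_dm=350, urine_L=1000, n_excreted_kg=20,
                          bedding_kg=500, grazing_share=1.0)
        assert b.housed_kg == pytest.approx(500.0)
        assert b.n_housed_kg == 0.0

    def test_no_grazing_no_bedding_no_sale(self):
        b = manure_budget(feces_kg_dm=35, urine_L=100, n_excreted_kg=2,
                          bedding_kg=0, grazing_share=0.0)
        # feces at 35% DM -> 100 kg fresh, plus 100 L urine
        assert b.housed_kg == pytest.approx(200.0)
        assert b.pasture_kg == 0.0

    def test_grazing_deposition_nutrients(self):
        out = grazing_manure_nutrients(1000.0)
        assert out["n_kg"] == pytest.approx(5.5)
        assert out["p_kg"] == pytest.approx(0.7)
        assert out["k_kg"] == pytest.approx(11.0)

    def test_oversold_rejected(self):
        with pytest.raises(ValueError, match="sold"):
            manure_budget(feces_kg_dm=35, urine_L=0, n_excreted_kg=1,
                          bedding_kg=0, grazing_share=0.0, sold_kg=500)

    @pytest.mark.parametrize("share", [0.0, 0.3, 0.7, 1.0])
    def test_pool_closure(self, share):
        """housed + pasture + sold == excreta + bedding, exactly."""
        b = manure_budget(feces_kg_dm=350, urine_L=1000, n_excreted_kg=20,
                          bedding_kg=500, grazing_share=share, sold_kg=100)
        produced = 350 / 0.35 + 1000 + 500
        assert b.housed_kg + b.pasture_kg + b.sold_kg == pytest.approx(produced)
        assert b.n_housed_kg + b.n_pasture_kg == pytest.approx(b.n_total_kg)


class TestFarmBalance:
    def test_meat_nutrient_factors(self, small_farm):
        farm = small_farm.model_copy(update={"live_weight_sold_kg": 1000.0})
        area = farm.total_ha
        bal = farm_n_p_balance(farm)
        assert bal["N"].items["out_meat"] * area == pytest.approx(280.0)
        assert bal["P"].items["out_meat"] * area == pytest.approx(6.5)

    def test_milk_nutrient_factors(self, small_farm):
        farm = small_farm.model_copy(update={"milk_sold_L": 1000.0})
        area = farm.total_ha
        bal = farm_n_p_balance(farm)
        # 1000 L x 1.034 kg/L x 5.8% CP / 6.38
        assert bal["N"].items["out_milk"] * area == pytest.approx(9.4, abs=0.05)
        assert bal["P"].items["out_milk"] * area == pytest.approx(1.3)

    def test_surplus_identity_exact(self, small_farm):
        for bal in farm_n_p_balance(small_farm).values():
            assert bal.surplus_kg_ha == bal.inputs_kg_ha - bal.outputs_kg_ha

    def test_conservation_on_synthetic_farms(self):
        from flockcarbon import gen_farm
        for seed in range(5):
            farm = gen_farm(seed, "Manchega")
            for bal in farm_n_p_balance(farm).values():
                assert (bal.inputs_kg_ha - bal.outputs_kg_ha
                        - bal.surplus_kg_ha) == 0.0

    def test_zero_area_rejected(self, small_farm):
        data = small_farm.model_dump()
        data["land"] = []
        data["communal_pasture_ha"] = 0.0
        from flockcarbon import FarmConfig
        with pytest.raises(ValueError, match="area"):
            farm_n_p_balance(FarmConfig.model_validate(data))

    def test_milk_n_helper(self):
        assert milk_n_kg(1000, 5.8) == pytest.approx(9.400, abs=0.001)


class TestSoilBalance:
    def test_extractions_equal_residues_zero_efficiency(self):
        sb = soil_balance("N", inputs_kg_ha=100, gaseous_losses_kg_ha=10,
                          leaching_kg_ha=10, extractions_kg_ha=30,
                          residues_kg_ha=30)
        assert sb.efficiency_pct == 0.0

    def test_quoted_formula_arithmetic(self):
        # inputs 100, balance 20 (outputs 80), extractions 60, residues 10
        sb = soil_balance("N", inputs_kg_ha=100, gaseous_losses_kg_ha=15,
                          leaching_kg_ha=5, extractions_kg_ha=60,
                          residues_kg_ha=10)
        assert sb.balance_kg_ha == pytest.approx(20.0)
        assert sb.efficiency_pct == pytest.approx(62.5)

    def test_closure_when_outputs_match_inputs(self):
        sb = soil_balance("P", inputs_kg_ha=50, gaseous_losses_kg_ha=0,
                          leaching_kg_ha=0, extractions_kg_ha=50)
        assert sb.balance_kg_ha == 0.0

    def test_undefined_efficiency_raises(self):
        sb = soil_balance("N", inputs_kg_ha=10, gaseous_losses_kg_ha=0,
                          leaching_kg_ha=0, extractions_kg_ha=0)
        with pytest.raises(ZeroDivisionError):
            sb.efficiency_pct
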