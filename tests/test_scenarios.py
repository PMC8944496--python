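import copy

import pytest

from flockcarbon import (
    BreedGroup, ScenarioGroup, ScenarioSpec, apply_scenario,
    genetic_value_reduction, run_scenarios, simulate, standard_scenarios,
    temperature_scenario,
)
from flockcarbon.scenarios import TEMPERATURE_RESPONSE_DEFAULT


def spec(group, **params):
    return ScenarioSpec("test", group, params)


class TestApplyScenario:
    def test_baseline_never_mutated(self, small_farm):
        before = small_farm.model_copy(deep=True)
        for s in standard_scenarios(small_farm.breed_group):
            apply_scenario(small_farm, s)
        assert small_farm == before

    def test_zero_delta_t_is_identity(self, small_farm):
        out = temperature_scenario(small_farm, 0.0)
        assert out == small_farm

    def test_breed_restriction_quoted(self, florida_farm):
        genetic = spec(ScenarioGroup.GENETIC_IMPROVEMENT, gv_increase_pct=10)
        genetic = ScenarioSpec("gv", ScenarioGroup.GENETIC_IMPROVEMENT,
                               {"gv_increase_pct": 10},
                               breeds=(BreedGroup.MANCHEGA,))
        with pytest.raises(ValueError, match="Manchega"):
            apply_scenario(florida_farm, genetic)

    def test_grazing_scenarios_not_in_goats(self, florida_farm):
        names = [s.name for s in standard_scenarios(BreedGroup.FLORIDA)]
        assert not any("Triticale grazing" in n for n in names)
        assert any("Triticale grazing" in s.name
                   for s in standard_scenarios(BreedGroup.MANCHEGA))

    def test_soybean_to_peas_moves_mass(self, small_farm):
        s = spec(ScenarioGroup.PURCHASED_FEED, kind="soybean_to_peas")
        out = apply_scenario(small_farm, s)
        assert out.purchases.soybean_kg == 0.0
        assert out.purchases.concentrate_kg == pytest.approx(
            small_farm.purchases.concentrate_kg
            + small_farm.purchases.soybean_kg)

    def test_soybean_to_peas_removes_soy_chain(self, small_farm):
        s = spec(ScenarioGroup.PURCHASED_FEED, kind="soybean_to_peas")
        out = simulate(apply_scenario(small_farm, s), soybean_feed="peas")
        assert out.report.sy_kg_co2e == 0.0


class TestGeneticImprovement:
    def test_zero_increase_removes_nobody(self):
        assert genetic_value_reduction(8.0, 0.0, 30000, 3000, 100) == 0

    def test_constructed_two_ewe_flock(self):
        """If the index gain adds exactly one ewe's production, one of two
        ewes becomes removable."""
        # per-ewe milk 100 L; slope 5.3 L per index point; a gain of
        # 50/5.3 points on each of 2 ewes frees one ewe's worth of milk
        gain_pts = 50.0 / 5.3
        gv0 = 10.0
        pct = gain_pts / gv0 * 100.0
        assert genetic_value_reduction(gv0, pct, 200.0, 0.0, 2) == 1

    @pytest.mark.parametrize("pct", [5, 10, 15])
    def test_reduction_fraction_in_reported_range(self, pct):
        """On a flock calibrated to the baseline (index ~8, ~340 L per ewe
        including suckled milk), index gains of 5-15% remove 0.47-2.38% of
        adults."""
        n = 1000
        milk_total = 342.0 * n
        removed = genetic_value_reduction(8.0, pct, milk_total, 0.0, n)
        frac = removed / n
        assert 0.0047 <= frac <= 0.0238

    def test_scenario_reduces_herd_not_milk(self, manchega_farm):
        s = ScenarioSpec("gv", ScenarioGroup.GENETIC_IMPROVEMENT,
                         {"gv_increase_pct": 10},
                         breeds=(BreedGroup.MANCHEGA,))
        out = apply_scenario(manchega_farm, s)
        assert out.herd.present_females < manchega_farm.herd.present_females
        assert out.milk_sold_L == manchega_farm.milk_sold_L


class TestTemperature:
    def test_default_response_calibration(self, small_farm):
        """A +2 degree year depresses milk by 0.46% under the default
        response table."""
        out = temperature_scenario(small_farm, 2.0)
        loss = 1.0 - out.milk_sold_L / small_farm.milk_sold_L
        assert loss == pytest.approx(0.0046, abs=1e-6)

    def test_loss_monotone_in_warming(self, small_farm):
        m1 = temperature_scenario(small_farm, 1.0).milk_sold_L
        m2 = temperature_scenario(small_farm, 2.0).milk_sold_L
        assert m2 < m1 < small_farm.milk_sold_L

    def test_missing_coefficient_named(self, small_farm):
        with pytest.raises(KeyError, match="milk_pct_per_degc"):
            temperature_scenario(small_farm, 2.0, response={})

    def test_climate_shifted(self, small_farm):
        out = temperature_scenario(small_farm, 2.0)
        assert out.climate[0].t_max == small_farm.climate[0].t_max + 2.0


class TestRunScenarios:
    def test_baseline_row_is_zero_change(self, small_farm):
        table = run_scenarios(small_farm, scenarios=[])
        row = table.iloc[0]
        assert row["scenario"] == "baseline"
        assert row["change_ha_pct"] == 0.0

    def test_extra_concentrate_raises_embedded_line_exactly(self, small_farm):
        purchases = small_farm.purchases.model_copy(update={
            "concentrate_kg": small_farm.purchases.concentrate_kg + 1000})
        plus = small_farm.model_copy(update={"purchases": purchases})
        base = simulate(small_farm)
        more = simulate(plus)
        delta = (more.ledger.category_total("purchased_concentrate")
                 - base.ledger.category_total("purchased_concentrate"))
        assert delta == pytest.approx(300.0)

    def test_milking_cut_scales_electricity_exactly(self, small_farm):
        s = spec(ScenarioGroup.ELECTRICAL_SUPPLY, milking_time_cut_pct=10)
        out = apply_scenario(small_farm, s)
        base = simulate(small_farm)
        cut = simulate(out)
        assert cut.ledger.category_total("purchased_electricity") == \
            pytest.approx(
                0.9 * base.ledger.category_total("purchased_electricity"))

    def test_full_catalogue_runs_without_errors(self, small_farm):
        table = run_scenarios(small_farm)
        assert "error" not in table.columns or table["error"].isna().all()
        assert len(table) == len(standard_scenarios(small_farm.breed_group)) + 1

    def test_purchase_side_scenarios_commute(self, small_farm):
        a = spec(ScenarioGroup.PURCHASED_FEED, kind="soybean_to_peas")
        b = spec(ScenarioGroup.ELECTRICAL_SUPPLY, milking_time_cut_pct=10)
        ab = apply_scenario(apply_scenario(small_farm, a), b)
        ba = apply_scenario(apply_scenario(small_farm, b), a)
        assert ab == ba
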