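import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockcarbon import (
    LinearModelSpec, demography, eval_linear, excreta_predict,
    excreta_replacement, fit_stepwise, forage_yield, gdd, gompertz_weight,
    milk_from_genetic_value,
)
from flockcarbon.empirical import (
    GOMPERTZ_GOAT, GOMPERTZ_SHEEP, N_URINE_MODEL, URINE_MODEL,
)


class TestEvalLinear:
    def test_all_zero_inputs_give_intercept(self):
        spec = LinearModelSpec("m", 3.5, {"a": 2.0, "b": -1.0})
        assert eval_linear(spec, {"a": 0, "b": 0}) == 3.5

    def test_missing_predictor_named(self):
        spec = LinearModelSpec("m", 0.0, {"a": 1.0, "b": 1.0})
        with pytest.raises(KeyError, match="'b'"):
            eval_linear(spec, {"a": 1})

    def test_fecal_n_at_mean_intake(self):
        """The fecal-N regression at the dataset-mean N intake of 20.9 g/d
        predicts 6.3 g/d of fecal N."""
        out = excreta_predict(omd=0.633, dmi_g=791.5, gp_g=143.8,
                              ndf_g=386.7, n_intake_g=20.9)
        assert round(out["n_feces_g"], 1) == 6.3

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_dot_product_oracle(self, data):
        k = data.draw(st.integers(1, 8))
        betas = data.draw(st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=k, max_size=k))
        xs = data.draw(st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=k, max_size=k))
        intercept = data.draw(st.floats(-1e3, 1e3, allow_nan=False))
        names = [f"x{i}" for i in range(k)]
        spec = LinearModelSpec("rnd", intercept, dict(zip(names, betas)))
        expected = intercept + float(np.dot(betas, xs))
        got = eval_linear(spec, dict(zip(names, xs)))
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestDemography:
    def test_zero_flock_clamps_to_zero(self):
        d = demography(0)
        assert d.replacement_females == 0
        assert d.raw["replacement_females"] == pytest.approx(-136.7)

    def test_born_at_reference_census(self):
        assert demography(1267).born_offspring == pytest.approx(2307.87)

    def test_culled_at_reference_census(self):
        assert demography(1267).culled_offspring == pytest.approx(1320.39)

    def test_negative_census_rejected(self):
        with pytest.raises(ValueError):
            demography(-1)


class TestExcreta:
    def test_feces_at_trial_means(self):
        out = excreta_predict(omd=0.633, dmi_g=791.5, gp_g=143.8,
                              ndf_g=386.7, n_intake_g=20.9)
        assert out["feces_g_dm"] == pytest.approx(337.1, abs=0.5)

    def test_urine_n_at_mean_intake(self):
        out = excreta_predict(omd=0.633, dmi_g=791.5, gp_g=143.8,
                              ndf_g=386.7, n_intake_g=20.9)
        assert out["n_urine_g"] == pytest.approx(15.33, abs=0.01)

    def test_cap_conserves_nitrogen(self):
        out = excreta_predict(omd=0.633, dmi_g=791.5, gp_g=143.8,
                              ndf_g=386.7, n_intake_g=20.9, cap_n=True)
        assert out["n_feces_g"] + out["n_urine_g"] <= 20.9 + 1e-12
        assert round(out["n_feces_g"], 1) == 6.3  # fecal N untouched by cap

    def test_percent_omd_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            excreta_predict(omd=63.3, dmi_g=791.5, gp_g=143.8,
                            ndf_g=386.7, n_intake_g=20.9)

    @pytest.mark.parametrize("x,feces,urine", [
        (0.0, 0.16, 0.0),
        (1.0, 0.46, 0.3039),
        (2.0, 0.76, 0.6139),
    ])
    def test_replacement_models(self, x, feces, urine):
        out = excreta_replacement(x)
        assert out["n_feces_g"] == pytest.approx(feces, abs=1e-9)
        assert out["n_urine_g"] == pytest.approx(urine, abs=1e-9)


class TestForageYield:
    def test_oats_at_mean_height(self):
        assert forage_yield("oats", 70.5) == pytest.approx(5264.0)

    def test_oats_clamps_at_line_root(self):
        assert forage_yield("oats", 23.5) == 0.0

    def test_triticale_at_trial_means(self):
        got = forage_yield("triticale", 82.4, days_to_ear=154.2,
                           n_basal_kg_ha=23.8)
        assert got == pytest.approx(5748.1, abs=0.5)

    def test_oats_ignores_extra_predictors_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            got = forage_yield("oats", 70.5, days_to_ear=150)
        assert got == pytest.approx(5264.0)
        assert any("ignores" in r.message for r in caplog.records)

    def test_triticale_requires_all_predictors(self):
        with pytest.raises(ValueError):
            forage_yield("triticale", 80.0)


class TestGompertz:
    def test_sheep_asymptote(self):
        assert gompertz_weight(GOMPERTZ_SHEEP, 1e7) == pytest.approx(68.59)

    def test_birth_weights(self):
        assert gompertz_weight(GOMPERTZ_SHEEP, 0) == pytest.approx(5.80, abs=0.01)
        assert gompertz_weight(GOMPERTZ_GOAT, 0) == pytest.approx(7.97, abs=0.01)

    @given(st.floats(0, 2000), st.floats(0.01, 500))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, t, dt):
        w1 = gompertz_weight(GOMPERTZ_SHEEP, t)
        w2 = gompertz_weight(GOMPERTZ_SHEEP, t + dt)
        assert w1 < w2 < GOMPERTZ_SHEEP.beta1


class TestHeatUnits:
    @pytest.mark.parametrize("tmax,tmin,expect", [
        (20, 10, 11.0), (4, 4, 0.0), (2, 0, 0.0)])
    def test_examples(self, tmax, tmin, expect):
        assert gdd(tmax, tmin) == expect

    def test_inverted_temperatures_rejected(self):
        with pytest.raises(ValueError):
            gdd(5, 10)


@pytest.mark.parametrize("gv,expect", [(0, 198.3), (10, 251.3), (-10, 145.3)])
def test_milk_from_genetic_value(gv, expect):
    assert milk_from_genetic_value(gv) == pytest.approx(expect)


class TestStepwise:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        res = fit_stepwise(df, "y", ["x"])
        assert res.spec.intercept == pytest.approx(1.0, abs=1e-8)
        assert res.spec.coefficients["x"] == pytest.approx(2.0, abs=1e-8)

    def test_collinear_candidates_admit_at_most_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": 2 * x, "y": x + rng.normal(0, 0.1, 60)})
        res = fit_stepwise(df, "y", ["a", "b"])
        assert len(res.spec.coefficients) <= 1

    def test_recovers_urine_slope_on_synthetic_trials(self):
        from flockcarbon import gen_metabolic_trials
        df = gen_metabolic_trials(313, seed=5)
        res = fit_stepwise(df, "urine_ml", ["n_intake_g"])
        slope = res.spec.coefficients["n_intake_g"]
        se = res.spec.residual_se / (
            np.sqrt(len(df)) * df["n_intake_g"].std(ddof=1))
        assert abs(slope - URINE_MODEL.coefficients["n_intake_g"]) < 2 * se

    def test_pure_noise_gives_intercept_only(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50),
                           "y": rng.normal(size=50)})
        res = fit_stepwise(df, "y", ["x"])
        # x is independent noise; with alpha=0.05 it should rarely enter
        assert res.spec.coefficients == {} or res.r2 < 0.15

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"x": [1, 2], "y": [1, 2]})
        with pytest.raises(ValueError):
            fit_stepwise(df, "y", ["x"])


def test_spec_rejects_impossible_n():
    with pytest.raises(ValueError):
        LinearModelSpec("bad", 0.0, {"a": 1.0, "b": 2.0}, 1.0, n=2)
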