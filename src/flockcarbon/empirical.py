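"""Printed empirical sub-models: herd demography, excreta, forage yield,
Gompertz growth, growing degree-days, milk from genetic value, and the
forward-stepwise regression procedure used to build them.

Every linear sub-model is expressed as a :class:`LinearModelSpec`
(intercept + named coefficients + residual SE + n), evaluated by a single
shared evaluator so that the model definitions live in one place and can
be overridden from a CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearModelSpec:
    """A fitted (or published) multiple linear regression.

    ``residual_se`` is the standard error of the estimate in the units of
    the response; ``n`` the number of fitted records.
    """

    name: str
    intercept: float
    coefficients: Mapping[str, float]
    residual_se: float = 0.0
    n: int = 0
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.residual_se < 0:
            raise ValueError("residual_se must be non-negative")
        if self.n and self.n < len(self.coefficients) + 1:
            raise ValueError(
                f"{self.name}: n={self.n} too small for "
                f"{len(self.coefficients)} coefficients"
            )


def eval_linear(spec: LinearModelSpec, inputs: Mapping[str, float]) -> float:
    """Evaluate ``intercept + sum(beta * x)`` for a named-predictor model.

    Raises ``KeyError`` naming the first missing predictor.
    """
    total = spec.intercept
    for term, beta in spec.coefficients.items():
        if term not in inputs:
            raise KeyError(f"model {spec.name!r} requires predictor {term!r}")
        total += beta * inputs[term]
    return total


# ---------------------------------------------------------------------------
# Published model catalogue.
#
# Where two printed versions of a coefficient disagree, the complete model
# string is taken as authoritative (it is the only place the full equation
# is printed); the alternative readings are kept in the packaged CSV so a
# user can flip them.
# ---------------------------------------------------------------------------

DEMOGRAPHY_MODELS: dict[str, LinearModelSpec] = {
    "replacement_females": LinearModelSpec(
        "replacement_females", -136.7, {"present_females": 0.42}, 271, 61, 0.65
    ),
    "born_offspring": LinearModelSpec(
        "born_offspring", -112.1, {"present_females": 1.91}, 392, 61, 0.95
    ),
    "culled_offspring": LinearModelSpec(
        "culled_offspring", 91.4, {"present_females": 0.97}, 326, 61, 0.87
    ),
    "adult_losses": LinearModelSpec(
        "adult_losses", 122.6, {"present_females": 0.40}, 189, 19, 0.80
    ),
    "offspring_deaths": LinearModelSpec(
        "offspring_deaths", -117.2, {"present_females": 0.55}, 377, 48, 0.59
    ),
}

# Feces model: the published form carries OMD in percent divided by 100,
# i.e. 523 - 692.6*(OMD%/100); with OMD held as a fraction this is simply
# 523 - 692.6*OMD_fraction.
FECES_MODEL = LinearModelSpec(
    "feces_g_dm",
    523.0,
    {"omd_pct_over_100": -692.6, "dmi_g": 0.084, "gp_g": 0.57, "ndf_g": 0.269},
    59.3,
    510,
    0.64,
)
URINE_MODEL = LinearModelSpec(
    "urine_ml", -654.1, {"n_intake_g": 71.3}, 529.0, 313, 0.56
)
N_FECES_MODEL = LinearModelSpec(
    "n_feces_g", 1.30, {"n_intake_g": 0.24}, 1.26, 510, 0.78
)
N_URINE_MODEL = LinearModelSpec(
    "n_urine_g", 1.95, {"n_intake_g": 0.64}, 4.06, 313, 0.64
)
# Replacement animals: N excretion per g N ingested per kg metabolic weight
N_FECES_REPL_MODEL = LinearModelSpec(
    "n_feces_repl_g", 0.16, {"n_per_met_wt": 0.3}, 0.065, 0, 0.91
)
N_URINE_REPL_MODEL = LinearModelSpec(
    "n_urine_repl_g", -0.0061, {"n_per_met_wt": 0.31}, 0.06, 0, 0.98
)
TRITICALE_MODEL = LinearModelSpec(
    "triticale_kg_dm_ha",
    -11952.0,
    {"height_cm": 133.2, "days_to_ear": 33.9, "n_basal_kg_ha": 62.9},
    669.0,
    59,
    0.93,
)
OATS_MODEL = LinearModelSpec(
    "oats_kg_dm_ha", -2632.0, {"height_cm": 112.0}, 1211.0, 35, 0.87
)
MILK_GV_MODEL = LinearModelSpec(
    "milk_per_lactation_L", 198.3, {"genetic_value": 5.3}, 24.2, 0, 0.89
)

ALL_MODELS: dict[str, LinearModelSpec] = {
    **DEMOGRAPHY_MODELS,
    FECES_MODEL.name: FECES_MODEL,
    URINE_MODEL.name: URINE_MODEL,
    N_FECES_MODEL.name: N_FECES_MODEL,
    N_URINE_MODEL.name: N_URINE_MODEL,
    N_FECES_REPL_MODEL.name: N_FECES_REPL_MODEL,
    N_URINE_REPL_MODEL.name: N_URINE_REPL_MODEL,
    TRITICALE_MODEL.name: TRITICALE_MODEL,
    OATS_MODEL.name: OATS_MODEL,
    MILK_GV_MODEL.name: MILK_GV_MODEL,
}


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth curve y = beta1 * exp(-beta2 * exp(-beta3 * t))."""

    beta1: float  # asymptotic live weight, kg
    beta2: float  # shape
    beta3: float  # rate, 1/day
    species: str = "sheep"

    def __post_init__(self) -> None:
        if self.beta1 <= 0 or self.beta3 <= 0:
            raise ValueError("beta1 and beta3 must be positive")


GOMPERTZ_SHEEP = GompertzParams(68.59, 2.47, 0.01, "sheep")
GOMPERTZ_GOAT = GompertzParams(53.3, 1.9, 0.0046, "goat")


@dataclass(frozen=True)
class DemographyCounts:
    replacement_females: float
    born_offspring: float
    culled_offspring: float
    adult_losses: float
    offspring_deaths: float
    raw: Mapping[str, float] = field(default_factory=dict)


def _clamp0(x: float) -> float:
    return x if x > 0 else 0.0


def demography(present_females: float) -> DemographyCounts:
    """Annual herd flows from the present-female census.

    Each flow is a published linear model in PF; negative raw predictions
    (small flocks, below the regression support) are clamped to zero and
    kept in ``raw`` for diagnostics.
    """
    if present_females < 0:
        raise ValueError("present_females must be non-negative")
    raw = {
        name: eval_linear(spec, {"present_females": present_females})
        for name, spec in DEMOGRAPHY_MODELS.items()
    }
    return DemographyCounts(
        replacement_females=_clamp0(raw["replacement_females"]),
        born_offspring=_clamp0(raw["born_offspring"]),
        culled_offspring=_clamp0(raw["culled_offspring"]),
        adult_losses=_clamp0(raw["adult_losses"]),
        offspring_deaths=_clamp0(raw["offspring_deaths"]),
        raw=raw,
    )


def excreta_predict(
    omd: float, dmi_g: float, gp_g: float, ndf_g: float, n_intake_g: float,
    cap_n: bool = False,
) -> dict[str, float]:
    """Adult excreta per head and day from diet quantity and quality.

    ``omd`` is organic-matter digestibility as a fraction in (0, 1]; intakes
    are grams per head per day.  The N regressions are independent fits and
    can jointly overshoot intake near the dataset mean; with ``cap_n`` the
    fecal prediction is kept and urinary N is capped to the residual pool
    (N intake minus fecal N), which whole-farm balances use to conserve
    mass.  By default the raw regression predictions are returned.
    """
    if not 0 < omd <= 1:
        raise ValueError(
            f"omd must be a fraction in (0, 1], got {omd}; pass 0.633 not 63.3"
        )
    for name, v in [("dmi_g", dmi_g), ("gp_g", gp_g), ("ndf_g", ndf_g),
                    ("n_intake_g", n_intake_g)]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    feces = eval_linear(
        FECES_MODEL,
        {"omd_pct_over_100": omd, "dmi_g": dmi_g, "gp_g": gp_g, "ndf_g": ndf_g},
    )
    urine = eval_linear(URINE_MODEL, {"n_intake_g": n_intake_g})
    n_feces = eval_linear(N_FECES_MODEL, {"n_intake_g": n_intake_g})
    n_urine = eval_linear(N_URINE_MODEL, {"n_intake_g": n_intake_g})
    n_feces, n_urine = _clamp0(n_feces), _clamp0(n_urine)
    if cap_n:
        if n_feces > n_intake_g:
            n_feces = n_intake_g
        if n_feces + n_urine > n_intake_g:
            n_urine = _clamp0(n_intake_g - n_feces)
    return {
        "feces_g_dm": _clamp0(feces),
        "urine_ml": _clamp0(urine),
        "n_feces_g": n_feces,
        "n_urine_g": n_urine,
    }


def excreta_replacement(n_intake_per_met_wt: float) -> dict[str, float]:
    """Growing-animal N excretion (g) per g N ingested per kg LW^0.75."""
    if n_intake_per_met_wt < 0:
        raise ValueError("n_intake_per_met_wt must be non-negative")
    x = {"n_per_met_wt": n_intake_per_met_wt}
    return {
        "n_feces_g": _clamp0(eval_linear(N_FECES_REPL_MODEL, x)),
        "n_urine_g": _clamp0(eval_linear(N_URINE_REPL_MODEL, x)),
    }


def forage_yield(
    crop: str,
    height_cm: float,
    days_to_ear: float | None = None,
    n_basal_kg_ha: float | None = None,
) -> float:
    """Winter-cereal forage yield (kg DM/ha) from agronomic predictors.

    Triticale uses plant height, days to ear emergence and basal N; oats
    uses height alone (extra arguments are ignored with a warning).
    """
    if height_cm <= 0:
        raise ValueError("height_cm must be positive")
    if crop == "triticale":
        if days_to_ear is None or n_basal_kg_ha is None:
            raise ValueError("triticale requires days_to_ear and n_basal_kg_ha")
        raw = eval_linear(
            TRITICALE_MODEL,
            {"height_cm": height_cm, "days_to_ear": days_to_ear,
             "n_basal_kg_ha": n_basal_kg_ha},
        )
    elif crop == "oats":
        if days_to_ear is not None or n_basal_kg_ha is not None:
            logger.warning("oats yield model ignores days_to_ear/n_basal_kg_ha")
        raw = eval_linear(OATS_MODEL, {"height_cm": height_cm})
    else:
        raise ValueError(f"unknown forage crop {crop!r}")
    return _clamp0(raw)


def gompertz_weight(params: GompertzParams, age_days: float) -> float:
    """Live weight (kg) at a given age; bounded above by beta1."""
    if age_days < 0:
        raise ValueError("age_days must be non-negative")
    return params.beta1 * math.exp(-params.beta2 * math.exp(-params.beta3 * age_days))


def gdd(t_max: float, t_min: float, t_base: float = 4.0) -> float:
    """Heat units (growing degree-days): max(0, (Tmax + Tmin)/2 - Tbase)."""
    if t_max < t_min:
        raise ValueError(f"t_max {t_max} < t_min {t_min}")
    return max(0.0, (t_max + t_min) / 2.0 - t_base)


def milk_from_genetic_value(gv: float) -> float:
    """Liters of milk per lactation from the flock genetic index."""
    return eval_linear(MILK_GV_MODEL, {"genetic_value": gv})


# ---------------------------------------------------------------------------
# Stepwise fitting
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    spec: LinearModelSpec
    vif: dict[str, float]
    durbin_watson: float
    r2: float
    standardized: dict[str, float]


def fit_stepwise(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
    max_vif: float = 10.0,
) -> StepwiseResult:
    """Forward stepwise OLS: at each step admit the candidate giving the
    highest R² among those significant at ``alpha`` and keeping every
    accepted predictor's variance inflation factor at or below ``max_vif``.

    Ties on R² are broken toward fewer predictors (a tie with the current
    model stops) and then lexically.  Returns the fitted model with
    residual SE, plus VIF per accepted predictor, the Durbin-Watson
    statistic of the residuals and standardized coefficients.
    """
    if len(data) < 10:
        raise ValueError("stepwise fitting needs at least 10 records")
    if not candidates:
        raise ValueError("no candidate predictors")
    y = data[response].to_numpy(dtype=float)
    selected: list[str] = []
    current_r2 = -np.inf
    remaining = sorted(candidates)
    while remaining:
        best: tuple[float, str] | None = None
        for cand in remaining:
            cols = selected + [cand]
            X = sm.add_constant(data[cols].to_numpy(dtype=float))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # perfectly collinear with current set
            fit = sm.OLS(y, X).fit()
            if fit.pvalues[-1] >= alpha:
                continue
            if len(cols) > 1:
                vifs = [
                    variance_inflation_factor(X[:, 1:], j)
                    for j in range(X.shape[1] - 1)
                ]
                if max(vifs) > max_vif:
                    continue
            if fit.rsquared > current_r2 + 1e-12 and (
                best is None or fit.rsquared > best[0] + 1e-12
            ):
                best = (fit.rsquared, cand)
        if best is None:
            break
        current_r2 = best[0]
        selected.append(best[1])
        remaining.remove(best[1])

    X = sm.add_constant(data[selected].to_numpy(dtype=float)) if selected else \
        np.ones((len(data), 1))
    fit = sm.OLS(y, X).fit()
    resid_se = float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0
    coefs = {p: float(b) for p, b in zip(selected, fit.params[1:])}
    std = {
        p: float(b * data[p].std(ddof=1) / data[response].std(ddof=1))
        for p, b in coefs.items()
    }
    vif = {}
    if len(selected) == 1:
        vif[selected[0]] = 1.0
    elif selected:
        Xp = data[selected].to_numpy(dtype=float)
        for j, p in enumerate(selected):
            vif[p] = float(variance_inflation_factor(Xp, j))
    spec = LinearModelSpec(
        name=response,
        intercept=float(fit.params[0]),
        coefficients=coefs,
        residual_se=resid_se,
        n=len(data),
        r2=float(fit.rsquared) if selected else 0.0,
    )
    return StepwiseResult(
        spec=spec,
        vif=vif,
        durbin_watson=float(durbin_watson(fit.resid)),
        r2=spec.r2,
        standardized=std,
    )
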