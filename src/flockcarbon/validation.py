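"""Model-evaluation battery: coefficient of determination, Willmott index
of agreement, RMSE, mean bias error (simulated - observed, so positive
means overestimation) and Nash-Sutcliffe model efficiency, plus the
collinearity diagnostics (variance inflation factors, Durbin-Watson) used
when building regression sub-models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson


@dataclass(frozen=True)
class ValidationReport:
    r2: float
    d: float       # Willmott index of agreement, [0, 1]
    rmse: float
    mbe: float     # mean(simulated - observed); > 0 = overestimation
    ef: float      # Nash-Sutcliffe efficiency, unbounded below, <= 1
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "d": self.d, "rmse": self.rmse,
                "mbe": self.mbe, "ef": self.ef, "n": self.n}


def validate(observed, simulated) -> ValidationReport:
    """Compare simulated against observed values with the five indices.

    Requires equal-length vectors of at least two records; a constant
    observed vector leaves EF and r2 undefined and raises.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("observed and simulated must be equal-length 1-D vectors")
    if obs.size < 2:
        raise ValueError("need at least two records")
    obs_mean = obs.mean()
    ss_obs = float(np.sum((obs - obs_mean) ** 2))
    if ss_obs == 0:
        raise ValueError("observed vector is constant: EF and r2 undefined")
    err = sim - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mbe = float(np.mean(err))
    ef = 1.0 - float(np.sum(err**2)) / ss_obs
    denom = float(np.sum((np.abs(sim - obs_mean) + np.abs(obs - obs_mean)) ** 2))
    d = 1.0 if denom == 0 else 1.0 - float(np.sum(err**2)) / denom
    d = min(1.0, max(0.0, d))  # clamp FP round-off; d is in [0, 1] by construction
    if np.all(sim == sim[0]):
        r2 = 0.0 if not np.all(err == 0) else 1.0
    else:
        r = float(np.corrcoef(obs, sim)[0, 1])
        r2 = r * r if math.isfinite(r) else 0.0
    return ValidationReport(r2=r2, d=d, rmse=rmse, mbe=mbe, ef=ef, n=obs.size)


def collinearity(design, residuals=None) -> dict[str, object]:
    """VIF per design column and (when residuals are given) the
    Durbin-Watson statistic.  Perfectly collinear columns are reported as
    infinite VIF with a flag rather than raising."""
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    n, k = X.shape
    vifs: list[float] = []
    full_rank = np.linalg.matrix_rank(X) == min(n, k)
    for j in range(k):
        if k == 1:
            vifs.append(1.0)
            continue
        if not full_rank:
            # check whether THIS column is explained exactly by the others
            others = np.delete(X, j, axis=1)
            beta, res, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            ssr = float(res[0]) if res.size else float(
                np.sum((X[:, j] - others @ beta) ** 2)
            )
            if ssr < 1e-10 * max(1.0, float(np.sum(X[:, j] ** 2))):
                vifs.append(float("inf"))
                continue
        vifs.append(float(variance_inflation_factor(X, j)))
    out: dict[str, object] = {
        "vif": vifs,
        "collinear": any(math.isinf(v) for v in vifs),
    }
    if residuals is not None:
        out["durbin_watson"] = float(durbin_watson(np.asarray(residuals, float)))
    return out
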