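"""Local sensitivity of calibration RMSE to each fitted parameter.

Each parameter is perturbed in turn by -5 % to +5 % in 1 % steps (the 0 %
step is excluded) with all other parameters held at their optimised values,
and the normalised sensitivity coefficient

    NSC = (dRMSE / RMSE_opt) / (dP / P_opt)

is evaluated for each perturbation.  Coefficients are averaged over the ten
perturbations into NSC_mean.  The headline NSC_mean is the mean of absolute
values (matching how sensitivity magnitudes are usually ranked); the signed
mean is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationConfig, _Objective
from .dynamics import FITTED_NAMES, ModelParams
from .errors import ColdHardinessError, ParameterError

__all__ = [
    "PERTURBATION_FRACTIONS",
    "SensitivityResult",
    "nsc_value",
    "nsc",
    "sensitivity_table",
]

#: the ten relative perturbations, -5 %..+5 % at 1 % steps, 0 excluded
PERTURBATION_FRACTIONS = tuple(p / 100.0 for p in (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5))


class UndefinedSensitivityError(ColdHardinessError, ZeroDivisionError):
    """RMSE at the optimum is zero, so relative changes are undefined."""


@dataclass
class SensitivityResult:
    """Per-parameter sensitivity detail.

    ``detail`` has one row per perturbation with columns
    fraction, value, rmse, delta_rmse_rel, nsc.
    """

    parameter: str
    detail: pd.DataFrame
    nsc_mean_abs: float
    nsc_mean_signed: float


def nsc_value(rmse_opt: float, rmse_perturbed: float, fraction: float) -> float:
    """Normalised sensitivity coefficient from two RMSE evaluations."""
    if rmse_opt <= 0:
        raise UndefinedSensitivityError("RMSE at the optimum must be > 0")
    if fraction == 0:
        raise ParameterError("zero perturbation gives an undefined coefficient")
    return ((rmse_perturbed - rmse_opt) / rmse_opt) / fraction


def nsc(
    param_name: str,
    fraction: float,
    params_opt: ModelParams,
    weather: pd.DataFrame,
    observations: pd.DataFrame,
    latitude: float,
    config: Optional[CalibrationConfig] = None,
) -> float:
    """NSC for one parameter perturbed by ``fraction`` (e.g. 0.01 = +1 %)."""
    if param_name not in FITTED_NAMES:
        raise ParameterError(f"{param_name!r} is not a fitted parameter")
    config = config or CalibrationConfig(seed=0)
    obj = _Objective(weather, observations, latitude, config)
    rmse_opt = obj.rmse_of(params_opt)
    perturbed = params_opt.replace(**{param_name: getattr(params_opt, param_name) * (1.0 + fraction)})
    return nsc_value(rmse_opt, obj.rmse_of(perturbed), fraction)


def sensitivity_table(
    params_opt: ModelParams,
    weather: pd.DataFrame,
    observations: pd.DataFrame,
    latitude: float,
    config: Optional[CalibrationConfig] = None,
) -> list[SensitivityResult]:
    """Full sensitivity analysis: one result per fitted parameter.

    ``lt10_ini`` is excluded (fixed, not fitted).  Deterministic: repeated
    runs on the same inputs give identical tables.
    """
    config = config or CalibrationConfig(seed=0)
    obj = _Objective(weather, observations, latitude, config)
    rmse_opt = obj.rmse_of(params_opt)
    if rmse_opt <= 0:
        raise UndefinedSensitivityError("RMSE at the optimum must be > 0")

    results = []
    for name in FITTED_NAMES:
        rows = []
        for frac in PERTURBATION_FRACTIONS:
            value = getattr(params_opt, name) * (1.0 + frac)
            r = obj.rmse_of(params_opt.replace(**{name: value}))
            rows.append(
                {
                    "fraction": frac,
                    "value": value,
                    "rmse": r,
                    "delta_rmse_rel": (r - rmse_opt) / rmse_opt,
                    "nsc": nsc_value(rmse_opt, r, frac),
                }
            )
        detail = pd.DataFrame(rows)
        results.append(
            SensitivityResult(
                parameter=name,
                detail=detail,
                nsc_mean_abs=float(np.mean(np.abs(detail["nsc"]))),
                nsc_mean_signed=float(np.mean(detail["nsc"])),
            )
        )
    return results


def summary_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    """One-row-per-parameter summary (parameter, nsc_mean_abs, nsc_mean_signed)."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "nsc_mean_abs": [r.nsc_mean_abs for r in results],
            "nsc_mean_signed": [r.nsc_mean_signed for r in results],
        }
    )
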