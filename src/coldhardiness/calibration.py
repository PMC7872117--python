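"""Parameter estimation by differential evolution and 2-fold cross-validation.

Nine parameters (all of :data:`~coldhardiness.dynamics.FITTED_NAMES`; the
baseline ``lt10_ini`` stays fixed at -2 degC) are fitted by minimising the
root mean square error between simulated and observed LT10 at the
observation dates, using the differential-evolution global optimiser.
Model validation uses 2-fold cross-validation: the observations are
randomly halved, each half is used to calibrate while the other validates,
and per-fold RMSE and squared Pearson correlation are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .dynamics import (
    FITTED_NAMES,
    ModelParams,
    _season_arrays,
    split_seasons,
)
from . import photoperiod as _photo
from .errors import DataError, ParameterError

__all__ = [
    "DEFAULT_BOUNDS",
    "CalibrationConfig",
    "FitResult",
    "CVFold",
    "rmse",
    "rmse_of_params",
    "fit_parameters",
    "two_fold_cv",
]

#: Generous envelopes around plausible tea-cultivar values (no published
#: bounds exist); units match ModelParams.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "t_th_ac": (5.0, 25.0),
    "h_ac": (0.001, 0.2),
    "csm_ac": (-1500.0, -50.0),
    "k": (1.0, 50.0),
    "c": (0.5, 6.0),
    "t_th_de": (-25.0, 15.0),
    "h_de": (0.001, 0.2),
    "csm_de": (-1500.0, -50.0),
    "p_de": (540.0, 780.0),
}


@dataclass
class CalibrationConfig:
    """Differential-evolution settings and parameter bounds.

    ``fixed`` maps parameter names to values held constant during the fit
    (``lt10_ini`` is always fixed, default -2 degC); every other ModelParams
    field is free within ``bounds``.  A seed is mandatory: runs are
    reproducible.
    """

    seed: int
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fixed: dict[str, float] = field(default_factory=lambda: {"lt10_ini": -2.0})
    popsize: int = 15
    maxiter: int = 300
    tol: float = 0.01
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.9
    polish: bool = True
    season_start: tuple[int, int] = (7, 1)
    transition_rule: str = "or"
    clip_warm_days: bool = True

    def __post_init__(self) -> None:
        if "lt10_ini" not in self.fixed:
            self.fixed = {"lt10_ini": -2.0, **self.fixed}
        for name, (lo, hi) in self.bounds.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ParameterError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def free_names(self) -> list[str]:
        return [n for n in FITTED_NAMES if n not in self.fixed]


@dataclass
class FitResult:
    params: ModelParams
    rmse: float
    trace: list[float]
    converged: bool
    n_iterations: int


@dataclass
class CVFold:
    calibration_rmse: float
    validation_rmse: float
    calibration_r2: float
    validation_r2: float
    params: ModelParams


def rmse(predicted, observed) -> float:
    """Root mean square error between matched prediction/observation pairs."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise DataError("predicted and observed must be equal-length, non-empty")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _r2(predicted, observed) -> float:
    """Squared Pearson correlation (nan when either side is constant)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size < 2 or np.std(p) == 0 or np.std(o) == 0:
        return float("nan")
    return float(np.corrcoef(p, o)[0, 1] ** 2)


class _Objective:
    """RMSE of a parameter vector, with all weather-dependent quantities
    (season splits, day lengths, observation-date indices) precomputed.

    The differential-evolution loop calls this thousands of times, so the
    per-call work is a handful of vector operations per season.
    """

    def __init__(
        self,
        weather: pd.DataFrame,
        observations: pd.DataFrame,
        latitude: float,
        config: CalibrationConfig,
    ):
        if not {"date", "lt10_c"} <= set(observations.columns):
            raise DataError("observations must have columns date,lt10_c")
        obs = observations.copy()
        obs["date"] = pd.to_datetime(obs["date"])
        self.config = config
        self.seasons = []
        matched = np.zeros(len(obs), dtype=bool)
        for chunk in split_seasons(weather, config.season_start):
            dates = chunk["date"]
            doy = dates.dt.dayofyear.to_numpy()
            dl = np.asarray(_photo.day_length_minutes(latitude, doy))
            inc = np.asarray(_photo.day_length_increasing(latitude, doy))
            pos = dates.searchsorted(obs["date"].to_numpy())
            pos = np.clip(pos, 0, len(dates) - 1)
            hit = dates.to_numpy()[pos] == obs["date"].to_numpy()
            matched |= hit
            self.seasons.append(
                {
                    "ta": chunk["tmean_c"].to_numpy(dtype=float),
                    "dl": dl,
                    "inc": inc,
                    "obs_idx": pos[hit],
                    "obs_val": obs["lt10_c"].to_numpy(dtype=float)[hit],
                }
            )
        if not matched.all():
            missing = obs.loc[~matched, "date"].dt.strftime("%Y-%m-%d").tolist()
            raise DataError(f"observation dates without simulated days: {missing}")
        self.n_obs = int(matched.sum())

    def build_params(self, x: np.ndarray) -> ModelParams:
        vals = dict(self.config.fixed)
        vals.update(zip(self.config.free_names, x))
        return ModelParams(**vals)

    def predict(self, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        pred, obs = [], []
        for s in self.seasons:
            if len(s["obs_idx"]) == 0:
                continue
            out = _season_arrays(
                s["ta"], s["inc"], s["dl"], params,
                clip_warm_days=self.config.clip_warm_days,
                transition_rule=self.config.transition_rule,
            )
            pred.append(out["lt10"][s["obs_idx"]])
            obs.append(s["obs_val"])
        return np.concatenate(pred), np.concatenate(obs)

    def rmse_of(self, params: ModelParams) -> float:
        p, o = self.predict(params)
        return rmse(p, o)

    def __call__(self, x: np.ndarray) -> float:
        return self.rmse_of(self.build_params(x))


def rmse_of_params(
    params: ModelParams,
    weather: pd.DataFrame,
    observations: pd.DataFrame,
    latitude: float,
    config: Optional[CalibrationConfig] = None,
) -> float:
    """RMSE of a given parameter set against dated observations."""
    config = config or CalibrationConfig(seed=0)
    return _Objective(weather, observations, latitude, config).rmse_of(params)


def fit_parameters(
    weather: pd.DataFrame,
    observations: pd.DataFrame,
    latitude: float,
    config: CalibrationConfig,
) -> FitResult:
    """Fit the free parameters by differential evolution.

    Returns the best parameter set found, its RMSE, and the per-generation
    best-objective trace (monotone non-increasing).  If the optimiser hits
    ``maxiter`` without meeting its tolerance the best-so-far result is
    returned with ``converged=False``.
    """
    if len(observations) < 2:
        raise DataError("need at least 2 observations to calibrate")
    obj = _Objective(weather, observations, latitude, config)
    names = config.free_names
    if not names:
        raise ParameterError("no free parameters to fit")
    missing = [n for n in names if n not in config.bounds]
    if missing:
        raise ParameterError(f"no bounds given for free parameters {missing}")
    bounds = [config.bounds[n] for n in names]

    trace: list[float] = []

    def record(intermediate_result):
        trace.append(float(intermediate_result.fun))

    res = optimize.differential_evolution(
        obj,
        bounds,
        seed=config.seed,
        popsize=config.popsize,
        maxiter=config.maxiter,
        tol=config.tol,
        mutation=config.mutation,
        recombination=config.recombination,
        polish=config.polish,
        updating="immediate",
        callback=record,
    )
    params = obj.build_params(res.x)
    return FitResult(
        params=params,
        rmse=float(res.fun),
        trace=trace,
        converged=bool(res.success),
        n_iterations=int(res.nit),
    )


def two_fold_cv(
    weather: pd.DataFrame,
    observations: pd.DataFrame,
    latitude: float,
    config: CalibrationConfig,
    seed: Optional[int] = None,
    partition_by: str = "observation",
) -> list[CVFold]:
    """2-fold cross-validation of the calibration.

    The observations are randomly split into halves d1/d2 (by individual
    observation by default; ``partition_by='season'`` splits whole seasons
    to avoid leaking within-season correlation).  The model is calibrated
    on each half and validated on the other; both folds are reported.
    """
    if len(observations) < 4:
        raise DataError("need at least 4 observations for 2-fold cross-validation")
    obs = observations.copy().reset_index(drop=True)
    obs["date"] = pd.to_datetime(obs["date"])
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if partition_by == "observation":
        perm = rng.permutation(len(obs))
        half = len(obs) // 2
        groups = [np.sort(perm[:half]), np.sort(perm[half:])]
    elif partition_by == "season":
        month, day = config.season_start
        boundary = obs["date"].dt.month * 100 + obs["date"].dt.day
        season_year = obs["date"].dt.year - (boundary < month * 100 + day)
        seasons = np.sort(season_year.unique())
        perm = rng.permutation(len(seasons))
        half = len(seasons) // 2
        s1 = set(seasons[perm[:half]])
        groups = [
            np.flatnonzero(season_year.isin(s1).to_numpy()),
            np.flatnonzero((~season_year.isin(s1)).to_numpy()),
        ]
    else:
        raise ParameterError("partition_by must be 'observation' or 'season'")

    folds = []
    for train_idx, test_idx in (groups, groups[::-1]):
        train, test = obs.iloc[train_idx], obs.iloc[test_idx]
        fit = fit_parameters(weather, train, latitude, config)
        obj_tr = _Objective(weather, train, latitude, config)
        obj_te = _Objective(weather, test, latitude, config)
        p_tr, o_tr = obj_tr.predict(fit.params)
        p_te, o_te = obj_te.predict(fit.params)
        folds.append(
            CVFold(
                calibration_rmse=rmse(p_tr, o_tr),
                validation_rmse=rmse(p_te, o_te),
                calibration_r2=_r2(p_tr, o_tr),
                validation_r2=_r2(p_te, o_te),
                params=fit.params,
            )
        )
    return folds
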