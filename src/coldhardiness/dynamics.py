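"""Daily cold-hardiness state machine.

Hardiness is tracked as LT10 (degC), updated once per day:

    LT10_t = LT10_{t-1} + dLT10.

The season runs through three phases:

pre-acclimation
    Before the first autumn day with mean temperature below the acclimation
    threshold T_th,ac.  LT10 stays at its unhardened baseline LT10_ini.
acclimation
    From the onset day, the cold-stress memory CSM (see :mod:`.memory`)
    deepens with accumulated below-threshold cold, and

        dLT10 = (CSM_t - CSM_{t-1}) * H_ac * S,

    where the slowdown factor S = 1 - CSM_{t-1}/CSM_ac (0 once the memory
    reaches its critical depth CSM_ac) reproduces the midwinter plateau of
    hardening.
deacclimation
    Entered permanently once CSM_{t-1} reaches the chilling-requirement
    level CSM_de or the photoperiod reaches its critical length P_de.  The
    driving state becomes the competition sigma_t = CSM_t + GDD_t between
    fading cold memory and growing degree days above T_th,de, with

        dLT10 = (sigma_t - sigma_{t-1}) * H_de.

    A cold snap deepens CSM faster than GDD grows, so dLT10 < 0: hardiness
    is partially regained (reacclimation) without leaving the phase.

LT10 is capped above at LT10_ini (the unhardened baseline) in every phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import photoperiod as _photo
from .errors import DataError, ParameterError
from .memory import ForgettingParams, MemoryConfig, csm_trajectory

__all__ = [
    "ModelParams",
    "SimulationResult",
    "PHASE_PRE",
    "PHASE_ACCLIMATION",
    "PHASE_DEACCLIMATION",
    "slowdown_factor",
    "acclimation_increment",
    "growing_degree_days",
    "deacclimation_increment",
    "detect_onset",
    "should_transition",
    "simulate",
    "split_seasons",
    "simulate_seasons",
]

PHASE_PRE = "pre_acclimation"
PHASE_ACCLIMATION = "acclimation"
PHASE_DEACCLIMATION = "deacclimation"

#: order of the fitted parameters (lt10_ini is fixed, not fitted)
FITTED_NAMES = ("t_th_ac", "h_ac", "csm_ac", "k", "c", "t_th_de", "h_de", "csm_de", "p_de")


@dataclass(frozen=True)
class ModelParams:
    """The ten parameters governing one cultivar's hardiness dynamics.

    Attributes
    ----------
    lt10_ini : float
        Unhardened baseline LT10 (degC, <= 0); fixed at -2 for tea buds.
    t_th_ac : float
        Threshold temperature effective for cold acclimation (degC).
    h_ac : float
        Acclimation rate constant (degC per degC of memory change), > 0.
    csm_ac : float
        Critical cold-stress memory at which acclimation halts (degC, < 0).
    k, c : float
        Forgetting-curve parameters (dimensionless, > 0).
    t_th_de : float
        Threshold temperature for deacclimation degree days (degC).
    h_de : float
        Deacclimation rate constant (degC per degC), > 0.
    csm_de : float
        Critical memory triggering the transition to deacclimation (degC, < 0).
    p_de : float
        Critical day length triggering the transition (minutes, 0-1440).
    """

    lt10_ini: float
    t_th_ac: float
    h_ac: float
    csm_ac: float
    k: float
    c: float
    t_th_de: float
    h_de: float
    csm_de: float
    p_de: float

    def __post_init__(self) -> None:
        if not self.lt10_ini <= 0:
            raise ParameterError(f"lt10_ini must be <= 0, got {self.lt10_ini}")
        for name in ("h_ac", "h_de", "k", "c"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("csm_ac", "csm_de"):
            if not getattr(self, name) < 0:
                raise ParameterError(f"{name} must be < 0, got {getattr(self, name)}")
        if not 0 < self.p_de < 1440:
            raise ParameterError(f"p_de must be in (0, 1440) minutes, got {self.p_de}")
        vals = [getattr(self, f) for f in self.__dataclass_fields__]
        if not np.all(np.isfinite(vals)):
            raise ParameterError(f"non-finite model parameter in {vals}")

    def memory_config(self, clip_warm_days: bool = True) -> MemoryConfig:
        return MemoryConfig(
            threshold_temperature=self.t_th_ac,
            forgetting=ForgettingParams(self.k, self.c),
            clip_warm_days=clip_warm_days,
        )

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class SimulationResult:
    """One season's daily trajectories plus phase bookkeeping.

    ``daily`` has one row per input day with columns
    date, tmean_c, lt10_c, csm_c, s, gdd_cday, phase.
    """

    daily: pd.DataFrame
    onset_date: Optional[pd.Timestamp]
    transition_date: Optional[pd.Timestamp]

    @property
    def lt10(self) -> pd.Series:
        return self.daily.set_index("date")["lt10_c"]


def slowdown_factor(csm_prev: float, csm_ac: float) -> float:
    """Acclimation slowdown S in [0, 1].

    S = 1 - CSM_{t-1}/CSM_ac while the memory is shallower than its
    critical level, and exactly 0 once CSM_{t-1} <= CSM_ac (both negative).
    """
    if not csm_ac < 0:
        raise ParameterError(f"csm_ac must be < 0, got {csm_ac}")
    if csm_prev <= csm_ac:
        return 0.0
    return 1.0 - csm_prev / csm_ac


def acclimation_increment(csm_t: float, csm_prev: float, h_ac: float, s: float) -> float:
    """Daily LT10 change during acclimation: (CSM_t - CSM_{t-1}) * H_ac * S."""
    return (csm_t - csm_prev) * h_ac * s


def growing_degree_days(temps, de_index: int, t: int, t_th_de: float) -> float:
    """Degree days above ``t_th_de`` accumulated from the deacclimation start.

    Daily contributions below the threshold are clipped to zero, so the sum
    is non-decreasing in ``t``.
    """
    if t < de_index:
        raise ParameterError(f"t ({t}) precedes deacclimation start ({de_index})")
    temps = np.asarray(temps, dtype=float)
    window = temps[de_index : t + 1]
    if len(window) != t - de_index + 1 or np.any(~np.isfinite(window)):
        raise DataError("temperature series does not cover the GDD window")
    return float(np.sum(np.maximum(window - t_th_de, 0.0)))


def deacclimation_increment(
    csm_t: float, csm_prev: float, gdd_t: float, gdd_prev: float, h_de: float
) -> float:
    """Daily LT10 change during deacclimation: d(CSM + GDD) * H_de."""
    return ((csm_t + gdd_t) - (csm_prev + gdd_prev)) * h_de


def detect_onset(temps, t_th_ac: float, start_index: int = 0) -> Optional[int]:
    """Index of the first day at/after ``start_index`` strictly below the
    acclimation threshold, or None if the series never crosses it."""
    temps = np.asarray(temps, dtype=float)
    if len(temps) == 0:
        raise DataError("empty temperature series")
    below = temps[start_index:] < t_th_ac
    if not below.any():
        return None
    return start_index + int(np.argmax(below))


def should_transition(
    csm_prev: float,
    csm_de: float,
    latitude: float,
    day_of_year: int,
    p_de: float,
    rule: str = "or",
) -> bool:
    """Whether the acclimation-to-deacclimation switch fires today.

    The chilling condition (CSM_{t-1} <= CSM_de) and the photoperiod
    condition (day length >= P_de while increasing) are combined with OR by
    default; ``rule='and'`` requires both.  Once true the phase change is
    permanent for the season (enforced by :func:`simulate`).
    """
    if not csm_de < 0:
        raise ParameterError(f"csm_de must be < 0, got {csm_de}")
    chill = csm_prev <= csm_de
    photo = _photo.photoperiod_trigger(latitude, day_of_year, p_de)
    if rule == "or":
        return bool(chill or photo)
    if rule == "and":
        return bool(chill and photo)
    raise ParameterError(f"transition rule must be 'or' or 'and', got {rule!r}")


# ---------------------------------------------------------------------------
# vectorised season core
# ---------------------------------------------------------------------------

def _season_arrays(
    ta: np.ndarray,
    photo_ok_given_inc: np.ndarray,
    dl: np.ndarray,
    p: ModelParams,
    *,
    clip_warm_days: bool = True,
    transition_rule: str = "or",
    onset_search_start: int = 0,
):
    """Run one season on plain arrays; returns a dict of daily arrays.

    ``dl`` is the day length in minutes for each day; ``photo_ok_given_inc``
    is the boolean "day length increasing" series.  Both are parameter-free
    and can be precomputed once per weather series (the calibration loop
    re-enters here thousands of times with different parameters).
    """
    n = len(ta)
    csm = np.zeros(n)
    gdd = np.zeros(n)
    s = np.ones(n)
    delta = np.zeros(n)

    onset = detect_onset(ta, p.t_th_ac, onset_search_start)
    de = None
    if onset is not None:
        csm[onset:] = csm_trajectory(ta, onset, p.memory_config(clip_warm_days))[onset:]
        csm_prev = np.zeros(n)
        csm_prev[onset + 1 :] = csm[onset:-1] if onset < n - 1 else []
        with np.errstate(invalid="ignore"):
            s = np.where(csm_prev > p.csm_ac, 1.0 - csm_prev / p.csm_ac, 0.0)

        photo = (dl >= p.p_de) & photo_ok_given_inc
        chill = csm_prev <= p.csm_de
        trig = (chill | photo) if transition_rule == "or" else (chill & photo)
        trig = trig & (np.arange(n) >= onset)
        de = int(np.argmax(trig)) if trig.any() else None

        acc_end = n if de is None else de
        sl = slice(onset, acc_end)
        delta[sl] = (csm[sl] - csm_prev[sl]) * p.h_ac * s[sl]

        if de is not None:
            g = np.cumsum(np.maximum(ta[de:] - p.t_th_de, 0.0))
            gdd[de:] = g
            sigma = csm[de:] + g
            sigma_prev = np.empty(len(sigma))
            sigma_prev[0] = csm_prev[de]  # GDD starts at zero on the transition day
            sigma_prev[1:] = sigma[:-1]
            delta[de:] = (sigma - sigma_prev) * p.h_de

    # LT10 with the lt10_ini upper cap applied at every step:
    # y_t = min(0, y_{t-1} + delta_t) == x_t - max(0, running max x)
    x = np.cumsum(delta)
    lt10 = p.lt10_ini + x - np.maximum(np.maximum.accumulate(x), 0.0)

    phase = np.full(n, PHASE_PRE, dtype=object)
    if onset is not None:
        phase[onset:] = PHASE_ACCLIMATION
        if de is not None:
            phase[de:] = PHASE_DEACCLIMATION

    return {
        "lt10": lt10,
        "csm": csm,
        "s": np.clip(s, 0.0, 1.0),
        "gdd": gdd,
        "phase": phase,
        "onset": onset,
        "de": de,
    }


def _validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    if not {"date", "tmean_c"} <= set(weather.columns):
        raise DataError("weather must have columns date,tmean_c")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    if len(w) == 0:
        raise DataError("empty weather series")
    gaps = w["date"].diff().dropna()
    if (gaps != pd.Timedelta(days=1)).any():
        bad = w["date"].iloc[int(np.argmax((gaps != pd.Timedelta(days=1)).to_numpy()))]
        raise DataError(f"weather dates not consecutive around {bad.date()}")
    if w["tmean_c"].isna().any() or ~np.isfinite(w["tmean_c"]).all():
        raise DataError("non-finite daily mean temperature in weather series")
    return w


def simulate(
    weather: pd.DataFrame,
    params: ModelParams,
    latitude: float,
    season_start_date=None,
    *,
    clip_warm_days: bool = True,
    transition_rule: str = "or",
) -> SimulationResult:
    """Simulate one season of daily LT10 from a consecutive weather series.

    Parameters
    ----------
    weather : DataFrame
        Columns ``date`` (consecutive calendar days) and ``tmean_c`` (degC).
    params : ModelParams
    latitude : float
        Site latitude, decimal degrees.
    season_start_date : date-like, optional
        Onset detection starts here (default: first weather date).
    clip_warm_days : bool
        Warm days contribute zero to CSM (default) rather than a positive term.
    transition_rule : {'or', 'and'}
        How the chilling and photoperiod transition conditions combine.

    Returns
    -------
    SimulationResult
    """
    w = _validate_weather(weather)
    ta = w["tmean_c"].to_numpy(dtype=float)
    doy = w["date"].dt.dayofyear.to_numpy()
    dl = np.asarray(_photo.day_length_minutes(latitude, doy))
    inc = np.asarray(_photo.day_length_increasing(latitude, doy))

    start = 0
    if season_start_date is not None:
        ts = pd.Timestamp(season_start_date)
        if not (w["date"].iloc[0] <= ts <= w["date"].iloc[-1]):
            raise DataError(f"season_start_date {ts.date()} outside weather coverage")
        start = int((w["date"] >= ts).idxmax() - w.index[0])

    out = _season_arrays(
        ta, inc, dl, params,
        clip_warm_days=clip_warm_days,
        transition_rule=transition_rule,
        onset_search_start=start,
    )
    daily = pd.DataFrame(
        {
            "date": w["date"].to_numpy(),
            "tmean_c": ta,
            "lt10_c": out["lt10"],
            "csm_c": out["csm"],
            "s": out["s"],
            "gdd_cday": out["gdd"],
            "phase": out["phase"],
        }
    )
    onset_date = None if out["onset"] is None else w["date"].iloc[out["onset"]]
    transition_date = None if out["de"] is None else w["date"].iloc[out["de"]]
    return SimulationResult(daily=daily, onset_date=onset_date, transition_date=transition_date)


def split_seasons(weather: pd.DataFrame, season_start=(7, 1)) -> list[pd.DataFrame]:
    """Split a multi-year weather series at the season-start month/day.

    Each chunk covers one hardiness season (default boundary 1 July, so a
    season spans 1 July - 30 June).  Leading partial seasons are kept.
    """
    w = _validate_weather(weather)
    month, day = season_start
    dates = w["date"]
    is_boundary = (dates.dt.month == month) & (dates.dt.day == day)
    idx = np.flatnonzero(is_boundary.to_numpy())
    cuts = [0] + [i for i in idx if i != 0] + [len(w)]
    return [w.iloc[a:b].reset_index(drop=True) for a, b in zip(cuts, cuts[1:]) if b > a]


def simulate_seasons(
    weather: pd.DataFrame,
    params: ModelParams,
    latitude: float,
    season_start=(7, 1),
    **kw,
) -> list[SimulationResult]:
    """Simulate every season in a multi-year series independently from
    ``lt10_ini`` (hardiness does not carry over the summer)."""
    return [simulate(chunk, params, latitude, **kw) for chunk in split_seasons(weather, season_start)]
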