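"""Independent slow-path oracles used to cross-check the implementation.

Everything here is deliberately written without reusing the package's
vectorised code paths: the memory oracle is a literal double loop, the
simulation oracle a literal day-by-day state machine, and the day-length
oracle a low-precision solar ephemeris (Astronomical Almanac) that shares
no formula with the package's Spencer-series declination.
"""

import math

import numpy as np

from coldhardiness.dynamics import ModelParams
from coldhardiness.photoperiod import photoperiod_trigger


def brute_weight(rank: int, k: float, c: float) -> float:
    return k / (math.log10(rank) ** c + k)


def brute_csm(temps, onset: int, t: int, t_th_ac: float, k: float, c: float,
              clip: bool = True) -> float:
    """Literal double-loop weighted sum over the memory window."""
    total = 0.0
    for n in range(onset, t + 1):
        d = temps[n] - t_th_ac
        if clip:
            d = min(d, 0.0)
        total += d * brute_weight(t - n + 1, k, c)
    return total


def brute_simulate(ta, doy, params: ModelParams, latitude: float,
                   clip: bool = True, rule: str = "or", start: int = 0):
    """Day-by-day recursion of the full model, recomputing CSM from scratch
    each day.  Returns (lt10, csm, phase, onset, de)."""
    n = len(ta)
    lt10 = np.empty(n)
    csm = np.zeros(n)
    phase = []
    state = "pre_acclimation"
    onset = de = None
    lt = params.lt10_ini
    sigma_prev = None
    for t in range(n):
        if state == "pre_acclimation" and t >= start and ta[t] < params.t_th_ac:
            state = "acclimation"
            onset = t
        csm_t = 0.0 if onset is None else brute_csm(ta, onset, t, params.t_th_ac,
                                                    params.k, params.c, clip)
        csm_prev = 0.0 if (onset is None or t == onset) else csm[t - 1]
        if state == "acclimation":
            chill = csm_prev <= params.csm_de
            photo = photoperiod_trigger(latitude, int(doy[t]), params.p_de)
            fire = (chill or photo) if rule == "or" else (chill and photo)
            if fire:
                state = "deacclimation"
                de = t
                sigma_prev = csm_prev  # GDD is zero just before the transition day
        if state == "acclimation":
            s = 0.0 if csm_prev <= params.csm_ac else 1.0 - csm_prev / params.csm_ac
            dlt = (csm_t - csm_prev) * params.h_ac * s
        elif state == "deacclimation":
            gdd_t = sum(max(ta[m] - params.t_th_de, 0.0) for m in range(de, t + 1))
            sigma_t = csm_t + gdd_t
            dlt = (sigma_t - sigma_prev) * params.h_de
            sigma_prev = sigma_t
        else:
            dlt = 0.0
        lt = min(params.lt10_ini, lt + dlt)
        lt10[t] = lt
        csm[t] = csm_t
        phase.append(state)
    return lt10, csm, phase, onset, de


def oracle_day_length(latitude: float, day_of_year, year_offset_days: float = 5478.5):
    """Day length (minutes) via the low-precision solar ephemeris.

    Mean longitude / mean anomaly -> ecliptic longitude -> declination.
    ``year_offset_days`` anchors day of year 1 to 2015-01-01 (days from
    J2000.0).
    """
    n = (np.asarray(day_of_year, dtype=float) - 1.0) + year_offset_days
    L = np.deg2rad((280.459 + 0.98564736 * n) % 360.0)
    g = np.deg2rad((357.529 + 0.98560028 * n) % 360.0)
    lam = L + np.deg2rad(1.915) * np.sin(g) + np.deg2rad(0.020) * np.sin(2 * g)
    eps = np.deg2rad(23.439 - 0.00000036 * n)
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    cos_ha = np.clip(-np.tan(np.deg2rad(latitude)) * np.tan(dec), -1.0, 1.0)
    return np.arccos(cos_ha) * 1440.0 / np.pi


def random_season_weather(rng: np.random.Generator, n_days: int = 200):
    """A plausible random autumn-to-spring temperature series (degC) plus
    day-of-year values, for oracle-equivalence checks."""
    mean = rng.uniform(12.0, 20.0)
    amp = rng.uniform(5.0, 12.0)
    phase0 = rng.uniform(0, 2 * np.pi)
    d = np.arange(n_days)
    ta = mean + amp * np.cos(2 * np.pi * d / 365.25 + phase0) + rng.normal(0, 2.0, n_days)
    start_doy = int(rng.integers(244, 305))  # season starts Sep-Oct
    doy = (start_doy + d - 1) % 365 + 1
    return ta, doy
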