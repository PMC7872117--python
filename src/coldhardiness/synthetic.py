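"""Synthetic daily weather and sparse hardiness observations.

The generator emulates the statistical structure the model expects from a
warm-temperate tea-growing site: an annual sinusoid in daily mean
temperature with AR(1)-autocorrelated residuals, optional superimposed
cold/warm spells, and weekly LT10 observations from November to April
obtained by running the dynamics model and adding homoscedastic Gaussian
measurement noise.

The ``kagoshima_like`` preset (annual mean 16 degC, amplitude 9 degC,
warmest day ~6 August, AR(1) phi 0.7, innovation SD 1.5 degC, latitude
31.37 N) produces winters that regularly cross both cultivars' acclimation
thresholds and cold-stress-memory depths comparable to the fitted critical
levels, so the full calibrate/validate pipeline is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import ModelParams, simulate_seasons
from .errors import ParameterError

__all__ = [
    "SyntheticWeatherConfig",
    "SyntheticObservationConfig",
    "Spell",
    "generate_weather",
    "generate_observations",
    "kagoshima_like",
    "KAGOSHIMA_LATITUDE",
]

KAGOSHIMA_LATITUDE = 31.37


@dataclass(frozen=True)
class Spell:
    """A sustained temperature anomaly: ``offset_c`` added for ``length_days``
    starting at ``start`` (overlapping spells sum)."""

    start: date
    length_days: int
    offset_c: float


@dataclass(frozen=True)
class SyntheticWeatherConfig:
    start: date
    end: date
    mean_c: float = 16.0
    amplitude_c: float = 9.0
    warmest_doy: int = 218
    ar1: float = 0.7
    innovation_sd_c: float = 1.5
    spells: Sequence[Spell] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_c < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.innovation_sd_c < 0:
            raise ParameterError("innovation SD must be >= 0")
        if not 0 <= self.ar1 < 1:
            raise ParameterError("AR(1) coefficient must be in [0, 1)")
        if self.end < self.start:
            raise ParameterError("end date precedes start date")


@dataclass(frozen=True)
class SyntheticObservationConfig:
    interval_days: int = 7
    window_start: tuple[int, int] = (11, 1)   # 1 November
    window_end: tuple[int, int] = (4, 30)     # 30 April
    noise_sd_c: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_days < 1:
            raise ParameterError("sampling interval must be >= 1 day")
        if self.noise_sd_c < 0:
            raise ParameterError("noise SD must be >= 0")


def generate_weather(config: SyntheticWeatherConfig) -> pd.DataFrame:
    """Daily mean temperature series: sinusoid + AR(1) noise + spells.

    T(d) = mean + amplitude * cos(2 pi (doy_d - warmest_doy) / 365.25) + e_d,
    e_d = phi * e_{d-1} + N(0, sd), with e_0 drawn from the stationary
    distribution so the series has no start-up transient.  Reproducible per
    seed; dates are consecutive with no gaps.
    """
    dates = pd.date_range(config.start, config.end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = config.mean_c + config.amplitude_c * np.cos(
        2.0 * np.pi * (doy - config.warmest_doy) / 365.25
    )

    rng = np.random.default_rng(config.seed)
    n = len(dates)
    noise = np.zeros(n)
    if config.innovation_sd_c > 0:
        innov = rng.normal(0.0, config.innovation_sd_c, size=n)
        stat_sd = config.innovation_sd_c / np.sqrt(1.0 - config.ar1**2)
        noise[0] = rng.normal(0.0, stat_sd)
        for i in range(1, n):
            noise[i] = config.ar1 * noise[i - 1] + innov[i]

    tmean = seasonal + noise
    for spell in config.spells:
        s0 = pd.Timestamp(spell.start)
        mask = (dates >= s0) & (dates < s0 + pd.Timedelta(days=spell.length_days))
        tmean = tmean + np.where(mask, spell.offset_c, 0.0)

    return pd.DataFrame({"date": dates, "tmean_c": tmean})


def _window_mask(dates: pd.Series, start_md: tuple[int, int], end_md: tuple[int, int]) -> np.ndarray:
    """Boolean mask for a month/day window that may wrap the year end."""
    md = dates.dt.month * 100 + dates.dt.day
    a = start_md[0] * 100 + start_md[1]
    b = end_md[0] * 100 + end_md[1]
    if a <= b:
        return ((md >= a) & (md <= b)).to_numpy()
    return ((md >= a) | (md <= b)).to_numpy()


def generate_observations(
    weather: pd.DataFrame,
    params: ModelParams,
    latitude: float,
    config: SyntheticObservationConfig,
    season_start=(7, 1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly (by default) noisy LT10 observations plus the noise-free truth.

    Runs the dynamics model over every season in ``weather``, samples the
    simulated LT10 every ``interval_days`` inside the observation window of
    each season, and adds centred Gaussian noise.

    Returns
    -------
    (observations, truth) : tuple of DataFrame
        ``observations`` has columns date,lt10_c (noisy, sampled);
        ``truth`` has the full noise-free daily trajectory date,lt10_c.
    """
    results = simulate_seasons(weather, params, latitude, season_start=season_start)
    truth = pd.concat([r.daily[["date", "lt10_c"]] for r in results], ignore_index=True)

    rng = np.random.default_rng(config.seed)
    frames = []
    for r in results:
        daily = r.daily
        mask = _window_mask(daily["date"], config.window_start, config.window_end)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        # sample every interval_days from the first in-window day, staying
        # inside contiguous stretches of the window
        take = idx[:: 1]
        sel = [take[0]]
        for i in take[1:]:
            if i - sel[-1] >= config.interval_days:
                sel.append(i)
        sub = daily.iloc[sel][["date", "lt10_c"]].copy()
        frames.append(sub)

    if not frames:
        return pd.DataFrame(columns=["date", "lt10_c"]), truth
    obs = pd.concat(frames, ignore_index=True)
    if config.noise_sd_c > 0:
        obs["lt10_c"] = obs["lt10_c"] + rng.normal(0.0, config.noise_sd_c, size=len(obs))
    return obs, truth


def kagoshima_like(
    start_year: int = 2015,
    n_seasons: int = 1,
    seed: int = 0,
    spells: Sequence[Spell] = (),
    **overrides,
) -> SyntheticWeatherConfig:
    """Weather-generator preset for a Kagoshima-like tea field.

    Covers ``n_seasons`` hardiness seasons starting 1 July of ``start_year``
    (each season runs to 30 June).
    """
    cfg = SyntheticWeatherConfig(
        start=date(start_year, 7, 1),
        end=date(start_year + n_seasons, 6, 30),
        seed=seed,
        spells=tuple(spells),
        **overrides,
    )
    return cfg
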