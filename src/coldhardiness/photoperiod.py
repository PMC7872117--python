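"""Geometric day length from latitude and day of year, and the critical
day-length trigger for the acclimation-to-deacclimation transition.

Day length is sunrise-to-sunset duration for the solar centre at zero
altitude (no refraction, twilight or elevation correction).  Solar
declination uses the Spencer Fourier series, accurate to ~0.2 deg, which
keeps day length within a couple of minutes of a full astronomical
calculation — adequate against critical-day-length thresholds that differ
between cultivars by only 7 min.

Latitudes are restricted to [-66, 66] deg so that sunrise and sunset exist
on every calendar day (no polar day/night).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

__all__ = ["MAX_LATITUDE", "solar_declination", "day_length_minutes", "photoperiod_trigger"]

MAX_LATITUDE = 66.0


def solar_declination(day_of_year):
    """Solar declination (radians) for a day of year, Spencer series."""
    g = 2.0 * np.pi * (np.asarray(day_of_year, dtype=float) - 1.0) / 365.0
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.001480 * np.sin(3 * g)
    )


def day_length_minutes(latitude: float, day_of_year):
    """Sunrise-to-sunset duration in minutes.

    Parameters
    ----------
    latitude : float
        Site latitude in decimal degrees, within [-66, 66].
    day_of_year : int or array_like of int
        Calendar day of year, 1-366.

    Returns
    -------
    float or ndarray
        Day length in minutes, in (0, 1440).
    """
    if abs(latitude) > MAX_LATITUDE:
        raise ParameterError(
            f"latitude {latitude} outside supported range [-{MAX_LATITUDE}, {MAX_LATITUDE}]"
        )
    doy = np.asarray(day_of_year)
    if np.any((doy < 1) | (doy > 366)):
        raise ParameterError(f"day_of_year must be in 1..366, got {day_of_year}")
    dec = solar_declination(doy)
    cos_ha = np.clip(-np.tan(np.deg2rad(latitude)) * np.tan(dec), -1.0, 1.0)
    minutes = np.arccos(cos_ha) * 1440.0 / np.pi
    if np.ndim(day_of_year) == 0:
        return float(minutes)
    return minutes


def _next_doy(day_of_year):
    """Following calendar day, wrapping the year end."""
    doy = np.asarray(day_of_year)
    return np.where(doy >= 365, 1, doy + 1)


def day_length_increasing(latitude: float, day_of_year):
    """True where tomorrow's day length exceeds today's (post winter solstice)."""
    today = day_length_minutes(latitude, day_of_year)
    tomorrow = day_length_minutes(latitude, _next_doy(day_of_year))
    inc = np.asarray(tomorrow) > np.asarray(today)
    if np.ndim(day_of_year) == 0:
        return bool(inc)
    return inc


def photoperiod_trigger(latitude: float, day_of_year, p_de: float):
    """Whether the critical day length ``p_de`` (minutes) has been reached.

    True iff the day length is at least ``p_de`` *and* day length is
    increasing (between winter and summer solstice).  The increasing-branch
    guard prevents the autumn crossing of an ~11 h threshold from starting
    deacclimation in November.
    """
    dl = day_length_minutes(latitude, day_of_year)
    inc = day_length_increasing(latitude, day_of_year)
    hit = (np.asarray(dl) >= p_de) & np.asarray(inc)
    if np.ndim(day_of_year) == 0:
        return bool(hit)
    return hit
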