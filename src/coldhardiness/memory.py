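"""Cold-stress memory (CSM): thermal time weighted by a forgetting curve.

The memory state of a bud on day ``t`` is the sum, over every day ``n`` since
the first autumn cold stress, of that day's temperature deficit below the
acclimation threshold, weighted by an Ebbinghaus-style forgetting curve

    w(r) = k / ((log10 r)^c + k),     r = t - n + 1,

where ``r`` is the elapsed rank of day ``n`` seen from day ``t`` (the most
recent day has rank 1 and full weight 1; the onset day has the largest rank
and the smallest weight).  ``k`` and ``c`` are dimensionless cultivar-specific
parameters: larger ``c`` (at given ``k``) makes the curve fall faster, i.e.
the plant weights recent cold more heavily relative to cold from months ago.

CSM is always <= 0 (units: degC day).  Days at or above the threshold
contribute zero, so under sustained warmth the memory shallows purely through
weight decay — the "forgetting" that drives spring deacclimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError

__all__ = [
    "ForgettingParams",
    "MemoryConfig",
    "forgetting_weight",
    "cold_stress_memory",
    "csm_trajectory",
]


@dataclass(frozen=True)
class ForgettingParams:
    """Forgetting-curve parameters.

    Attributes
    ----------
    k : float
        Positive dimensionless scale; larger ``k`` flattens the curve
        (slower forgetting).
    c : float
        Positive dimensionless exponent on ``log10`` of the elapsed rank.
    """

    k: float
    c: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and np.isfinite(self.k)):
            raise ParameterError(f"k must be finite and > 0, got {self.k}")
        if not (self.c > 0 and np.isfinite(self.c)):
            raise ParameterError(f"c must be finite and > 0, got {self.c}")


@dataclass(frozen=True)
class MemoryConfig:
    """Configuration of the cold-stress-memory accumulation.

    Attributes
    ----------
    threshold_temperature : float
        Acclimation threshold temperature (degC); only days strictly below
        it contribute to the memory.
    forgetting : ForgettingParams
        Parameters of the forgetting curve.
    clip_warm_days : bool
        If True (default), days at/above the threshold contribute exactly
        zero.  If False, their positive excess enters the sum — an
        alternative literal reading of the accumulation kept for comparison.
    """

    threshold_temperature: float
    forgetting: ForgettingParams = field(default_factory=lambda: ForgettingParams(18.7, 3.4))
    clip_warm_days: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_temperature):
            raise ParameterError("threshold_temperature must be finite")


def forgetting_weight(elapsed_rank, params: ForgettingParams):
    """Weight of a past day's cold stress, ``k / ((log10 r)^c + k)``.

    Parameters
    ----------
    elapsed_rank : int or array_like of int
        Rank ``r = t - n + 1`` of the past day ``n`` seen from the current
        day ``t``; the current day has rank 1.  Must be >= 1.
    params : ForgettingParams

    Returns
    -------
    float or ndarray
        Weight in (0, 1]; exactly 1 at rank 1 and strictly decreasing in
        the rank.
    """
    r = np.asarray(elapsed_rank, dtype=float)
    if np.any(r < 1):
        raise ParameterError(f"elapsed_rank must be >= 1, got {elapsed_rank}")
    w = params.k / (np.log10(r) ** params.c + params.k)
    if np.ndim(elapsed_rank) == 0:
        return float(w)
    return w


def _weights(n: int, params: ForgettingParams) -> np.ndarray:
    """Weights for ranks ``1..n`` (vectorised helper)."""
    return params.k / (np.log10(np.arange(1.0, n + 1.0)) ** params.c + params.k)


def _deficits(temps: np.ndarray, config: MemoryConfig) -> np.ndarray:
    d = temps - config.threshold_temperature
    if config.clip_warm_days:
        d = np.minimum(d, 0.0)
    return d


def cold_stress_memory(temps, onset_index: int, t: int, config: MemoryConfig) -> float:
    """CSM on day ``t``: weighted sum of below-threshold deficits since onset.

    Parameters
    ----------
    temps : array_like
        Daily mean temperatures (degC) indexed from day 0; must cover
        ``[onset_index, t]`` without missing values.
    onset_index : int
        Index of the first cold-stress day (start of accumulation).
    t : int
        Current day index (>= onset_index).
    config : MemoryConfig

    Returns
    -------
    float
        CSM_t <= 0 (degC day); exactly 0 when no day in the window is below
        the threshold.
    """
    if t < onset_index:
        raise ParameterError(f"t ({t}) precedes onset_index ({onset_index})")
    temps = np.asarray(temps, dtype=float)
    if onset_index < 0 or t >= len(temps):
        raise DataError(
            f"window [{onset_index}, {t}] not covered by series of length {len(temps)}"
        )
    window = temps[onset_index : t + 1]
    if np.any(~np.isfinite(window)):
        raise DataError("missing/non-finite temperature inside the memory window")
    d = _deficits(window, config)
    # day n has rank t-n+1: reverse the window so deficits align with ranks 1..m
    w = _weights(len(window), config.forgetting)
    return float(np.dot(d[::-1], w))


def csm_trajectory(temps, onset_index: int, config: MemoryConfig) -> np.ndarray:
    """Daily CSM series over the whole input, recomputed for each day.

    The forgetting weights depend on the current day ``t``, so the series is
    not a running sum: each element re-weights the full history.  Entries
    before ``onset_index`` are 0.

    Implemented as a discrete convolution of the deficit series with the
    weight sequence, which equals the O(t^2) day-by-day recomputation.
    """
    temps = np.asarray(temps, dtype=float)
    if len(temps) == 0:
        raise DataError("empty temperature series")
    if not (0 <= onset_index < len(temps)):
        raise ParameterError(f"onset_index {onset_index} outside series")
    if np.any(~np.isfinite(temps[onset_index:])):
        raise DataError("missing/non-finite temperature after onset")
    out = np.zeros(len(temps))
    d = _deficits(temps[onset_index:], config)
    w = _weights(len(d), config.forgetting)
    out[onset_index:] = np.convolve(d, w)[: len(d)]
    return out
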