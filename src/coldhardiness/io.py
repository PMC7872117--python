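"""Readers and writers for the package's CSV/YAML interchange formats.

All temperatures are degC, day lengths minutes, dates ISO-8601 calendar
days.  Weather CSVs carry ``date,tmean_c``; observation CSVs carry
``date,lt10_c``; simulation output carries one row per day with the full
diagnostic state.  Parameter sets are flat YAML mappings; the two cultivar
presets shipped with the package ('yabukita', 'yutakamidori') encode the
published parameter values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams, SimulationResult
from .errors import DataError

__all__ = [
    "read_weather",
    "read_observations",
    "write_simulation",
    "load_params",
    "save_params",
    "available_presets",
]

_TEMP_SANITY = (-50.0, 50.0)


def read_weather(path) -> pd.DataFrame:
    """Read and validate a daily weather CSV (columns date,tmean_c).

    Dates must be strictly consecutive calendar days; gaps and duplicates
    are rejected with the offending date named.  Floats are parsed with
    round-trip precision so write/read cycles are lossless.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"date", "tmean_c"} <= set(df.columns):
        raise DataError(f"{path}: weather file must have header date,tmean_c")
    if len(df) == 0:
        raise DataError(f"{path}: weather file has a header but no data rows")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as e:
        raise DataError(f"{path}: unparseable date ({e})") from e

    tmean = pd.to_numeric(df["tmean_c"], errors="coerce")
    bad = np.flatnonzero(tmean.isna().to_numpy())
    if len(bad):
        raise DataError(f"{path}: non-numeric tmean_c at data line {bad[0] + 2}")
    df["tmean_c"] = tmean.astype(float)

    dup = df["date"].duplicated()
    if dup.any():
        raise DataError(f"{path}: duplicate date {df['date'][dup].iloc[0].date()}")
    deltas = df["date"].diff().dropna()
    gaps = deltas != pd.Timedelta(days=1)
    if gaps.any():
        i = int(np.argmax(gaps.to_numpy()))
        missing = df["date"].iloc[i] + pd.Timedelta(days=1)
        raise DataError(f"{path}: gap in daily series; missing {missing.date()}")
    lo, hi = _TEMP_SANITY
    out_of_range = (df["tmean_c"] < lo) | (df["tmean_c"] > hi)
    if out_of_range.any():
        raise DataError(
            f"{path}: tmean_c outside sanity bounds [{lo}, {hi}] on "
            f"{df['date'][out_of_range].iloc[0].date()}"
        )
    return df[["date", "tmean_c"]]


def read_observations(path) -> pd.DataFrame:
    """Read and validate an LT10 observation CSV (columns date,lt10_c)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"date", "lt10_c"} <= set(df.columns):
        raise DataError(f"{path}: observation file must have header date,lt10_c")
    if len(df) == 0:
        raise DataError(f"{path}: observation file has no data rows")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as e:
        raise DataError(f"{path}: unparseable date ({e})") from e
    lt10 = pd.to_numeric(df["lt10_c"], errors="coerce")
    bad = np.flatnonzero(lt10.isna().to_numpy())
    if len(bad):
        raise DataError(f"{path}: non-numeric lt10_c at data line {bad[0] + 2}")
    if (lt10 > 0).any():
        raise DataError(f"{path}: positive lt10_c value {lt10[lt10 > 0].iloc[0]} (LT10 is <= 0)")
    if df["date"].duplicated().any():
        d = df["date"][df["date"].duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate observation date {d.date()}")
    df["lt10_c"] = lt10.astype(float)
    return df.sort_values("date").reset_index(drop=True)[["date", "lt10_c"]]


def write_simulation(result: SimulationResult, path) -> None:
    """Write one season's daily simulation output as CSV."""
    daily = result.daily.copy()
    daily["date"] = daily["date"].dt.strftime("%Y-%m-%d")
    daily.to_csv(path, index=False)


_PARAM_KEYS = [
    "lt10_ini", "t_th_ac", "h_ac", "csm_ac", "k", "c",
    "t_th_de", "h_de", "csm_de", "p_de",
]


def load_params(source) -> ModelParams:
    """Load a parameter set from a YAML file path or a preset name.

    ``source`` may be a filesystem path or one of the bundled preset names
    (see :func:`available_presets`).
    """
    path = Path(source)
    if path.exists():
        text = path.read_text()
    else:
        preset = resources.files("coldhardiness") / "presets" / f"{source}.yaml"
        if not preset.is_file():
            raise DataError(
                f"{source!r} is neither an existing file nor a preset "
                f"(presets: {', '.join(available_presets())})"
            )
        text = preset.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise DataError(f"{source}: parameter file must be a flat mapping")
    missing = [k for k in _PARAM_KEYS if k not in data]
    if missing:
        raise DataError(f"{source}: missing parameter keys {missing}")
    extra = set(data) - set(_PARAM_KEYS) - {"name"}
    if extra:
        raise DataError(f"{source}: unknown parameter keys {sorted(extra)}")
    return ModelParams(**{k: float(data[k]) for k in _PARAM_KEYS})


def save_params(params: ModelParams, path, name: str | None = None) -> None:
    """Write a parameter set as flat YAML (lossless double precision)."""
    data = {} if name is None else {"name": name}
    data.update({k: float(getattr(params, k)) for k in _PARAM_KEYS})
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def available_presets() -> list[str]:
    d = resources.files("coldhardiness") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in d.iterdir() if p.name.endswith(".yaml"))
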