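"""Controlled-freezing visual-scoring statistic and the LT10 decision rule.

After a programmed freeze to a target temperature, dissected buds are scored
for discoloration in four classes (score 0: no discoloration; 0.25: 1-33 %;
0.5: 34-66 %; 1: 67-100 %).  The percent-dead statistic for a subsample is
the score-weighted fraction of buds, and the cold-hardiness indicator LT10
is the lowest target temperature at which no more than 10 % of the sample
is dead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DataError, HardinessNotDeterminedError

__all__ = [
    "ScoreCounts",
    "percent_dead",
    "lt10_from_tests",
    "read_freezing_tests",
    "score_freezing_tests",
]

log = logging.getLogger(__name__)

_SCORE_WEIGHTS = (0.0, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class ScoreCounts:
    """Bud counts per discoloration class for one freezing-test subsample."""

    n0: int
    n025: int
    n05: int
    n1: int

    def __post_init__(self) -> None:
        counts = (self.n0, self.n025, self.n05, self.n1)
        if any(int(c) != c or c < 0 for c in counts):
            raise DataError(f"counts must be non-negative integers, got {counts}")

    @property
    def total(self) -> int:
        return self.n0 + self.n025 + self.n05 + self.n1


def percent_dead(counts: ScoreCounts) -> float:
    """Percentage of dead samples, the score-weighted bud fraction x 100."""
    n = counts.total
    if n == 0:
        raise DataError("freezing-test subsample has zero buds")
    weighted = sum(
        w * c for w, c in zip(_SCORE_WEIGHTS, (counts.n0, counts.n025, counts.n05, counts.n1))
    )
    return weighted / n * 100.0


def lt10_from_tests(tests, threshold_percent: float = 10.0) -> float:
    """LT10 from one sampling date's set of (target temperature, counts).

    Returns the lowest (most negative) target temperature whose percent-dead
    value does not exceed ``threshold_percent`` (inclusive).  With a
    non-monotone damage profile (deeper freeze scoring *less* damage —
    sampling noise) the most negative qualifying temperature still wins and
    a warning is logged.

    Raises
    ------
    HardinessNotDeterminedError
        If every target temperature exceeds the damage threshold; the caller
        may record the date as censored.
    """
    tests = list(tests)
    if not tests:
        raise DataError("empty freezing-test set")
    temps = [t for t, _ in tests]
    if len(set(temps)) != len(temps):
        raise DataError(f"duplicate target temperatures in freezing-test set: {temps}")
    damage = {t: percent_dead(c) for t, c in tests}
    qualifying = [t for t, p in damage.items() if p <= threshold_percent]
    if not qualifying:
        raise HardinessNotDeterminedError(
            f"all subsamples exceed {threshold_percent} % damage; LT10 undetermined"
        )
    # non-monotone check: damage should not decrease as temperature drops
    by_temp = sorted(damage.items(), key=lambda kv: kv[0], reverse=True)
    profile = [p for _, p in by_temp]
    if any(b < a for a, b in zip(profile, profile[1:])):
        log.warning("non-monotone damage profile %s; using most negative qualifying temperature", by_temp)
    return float(min(qualifying))


def read_freezing_tests(path) -> pd.DataFrame:
    """Read a freezing-test CSV (date,target_temp_c,n0,n025,n05,n1)."""
    df = pd.read_csv(path)
    required = ["date", "target_temp_c", "n0", "n025", "n05", "n1"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"freezing-test file {path} missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def score_freezing_tests(df: pd.DataFrame, threshold_percent: float = 10.0) -> pd.DataFrame:
    """Convert freezing-test records into dated LT10 observations.

    Dates at which no subsample qualifies are skipped with a warning (they
    are censored: hardiness exceeded the deepest freeze tested ... or the
    sample was too damaged throughout).
    """
    rows = []
    for date, group in df.groupby("date"):
        tests = [
            (float(r.target_temp_c), ScoreCounts(int(r.n0), int(r.n025), int(r.n05), int(r.n1)))
            for r in group.itertuples()
        ]
        try:
            rows.append({"date": date, "lt10_c": lt10_from_tests(tests, threshold_percent)})
        except HardinessNotDeterminedError:
            log.warning("no LT10 determined for %s; observation censored", date)
    return pd.DataFrame(rows, columns=["date", "lt10_c"])
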