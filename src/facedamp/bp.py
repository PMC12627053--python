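"""Blood-pressure reading aggregation and JNC-7 categorisation.

The study protocol takes four automated readings per day on two consecutive
days.  Because the first reading of a session is systematically elevated,
the first reading of each day is discarded and the remaining six are
averaged; the six-reading mean SBP/DBP is then categorised against the
JNC-7 bands: normotensive (SBP < 120 and DBP < 80), prehypertensive
(SBP 120-139 and/or DBP 80-89), stage-1 hypertensive (SBP 140-159 and/or
DBP 90-99).  Means at stage-2 levels (SBP >= 160 or DBP >= 100) fall
outside the recruited range and are flagged ``out_of_range``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

NORMOTENSIVE = "normotensive"
PREHYPERTENSIVE = "prehypertensive"
HYPERTENSIVE_S1 = "hypertensive_stage1"
OUT_OF_RANGE = "out_of_range"

#: JNC-7 categories in severity order (used by group tables and simulation).
CATEGORIES = (NORMOTENSIVE, PREHYPERTENSIVE, HYPERTENSIVE_S1)


@dataclass(frozen=True)
class BPReading:
    """A single cuff reading: day (1 or 2), index within day (1-based), mmHg."""

    day: int
    index_within_day: int
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if self.day not in (1, 2):
            raise ValueError(f"day must be 1 or 2, got {self.day}")
        if self.index_within_day < 1:
            raise ValueError("index_within_day is 1-based")
        if not 50 <= self.sbp <= 260:
            raise ValueError(f"SBP {self.sbp} outside plausible range [50, 260]")
        if not 30 <= self.dbp <= 150:
            raise ValueError(f"DBP {self.dbp} outside plausible range [30, 150]")
        if self.dbp >= self.sbp:
            raise ValueError(f"DBP {self.dbp} must be below SBP {self.sbp}")


def average_readings(
    readings: Iterable[BPReading], per_day: int = 4
) -> tuple[float, float]:
    """Mean (SBP, DBP) after discarding the first reading of each day.

    Requires exactly ``per_day`` readings on each of days 1 and 2; raises
    ``ValueError`` naming the offending day otherwise.
    """
    readings = list(readings)
    for day in (1, 2):
        n = sum(r.day == day for r in readings)
        if n != per_day:
            raise ValueError(f"day {day} has {n} readings, expected {per_day}")
    kept = [r for r in readings if r.index_within_day != 1]
    mean_sbp = sum(r.sbp for r in kept) / len(kept)
    mean_dbp = sum(r.dbp for r in kept) / len(kept)
    return mean_sbp, mean_dbp


def classify_jnc7(sbp: float, dbp: float) -> str:
    """JNC-7 category of a mean (SBP, DBP) pair.

    Normotensive requires BOTH pressures below threshold; the elevated
    categories trigger on EITHER ("and/or").  Bands are checked from the
    top down (out-of-range, then stage 1, then prehypertensive) so that a
    mixed profile (e.g. SBP 135 with DBP 92) lands in the higher stage and
    the category is monotone in both pressures.
    """
    if sbp >= 160 or dbp >= 100:
        return OUT_OF_RANGE
    if sbp >= 140 or dbp >= 90:
        return HYPERTENSIVE_S1
    if sbp >= 120 or dbp >= 80:
        return PREHYPERTENSIVE
    return NORMOTENSIVE


@dataclass(frozen=True)
class BPProfile:
    """Aggregated blood pressure of one participant."""

    readings: Sequence[BPReading]
    mean_sbp: float
    mean_dbp: float
    category: str

    @classmethod
    def from_readings(cls, readings: Iterable[BPReading]) -> "BPProfile":
        readings = tuple(readings)
        sbp, dbp = average_readings(readings)
        return cls(readings, sbp, dbp, classify_jnc7(sbp, dbp))
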