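"""Sleep-diary data model, per-day/per-participant summaries, and CSV I/O.

Clock times live on a *noon-to-noon* axis: hours after midnight of the diary
date, restricted to [12, 36). A bedtime of 25.85 means 01:51 the next calendar
day; this representation removes the midnight wraparound that plagues naive
clock arithmetic. The conventional [0, 24) display form is ``h % 24``.

Daily total sleep time (TST) is defined as

    TST = sleep-period duration − night-awakening minutes + nap minutes,

clamped at zero: wake-after-sleep-onset is excluded and daytime naps are
included, the conventional reading of "total sleep time" for diary data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDayError, NoDataError, ValidationError

__all__ = [
    "DiaryDay",
    "Diary",
    "daily_tst",
    "average_tst",
    "mean_clock_time",
    "display_clock_time",
    "read_diary_csv",
    "write_diary_csv",
    "participant_summary",
]

DIARY_COLUMNS = [
    "participant_id",
    "day_index",
    "bedtime_h",
    "waketime_h",
    "n_awakenings",
    "awake_min",
    "n_naps",
    "nap_min",
    "missing",
]


@dataclass(frozen=True)
class DiaryDay:
    """One diary night: bed/wake clock times plus nap and awakening totals.

    ``bedtime`` and ``waketime`` are hours on the noon-to-noon axis
    ([12, 36)). The diary records the *number and total duration* of naps
    and night awakenings, not their timing.
    """

    participant_id: str
    day_index: int
    bedtime: float
    waketime: float
    n_awakenings: int = 0
    awake_min: float = 0.0
    n_naps: int = 0
    nap_min: float = 0.0
    missing: bool = False

    def validate(self, strict: bool = True) -> "DiaryDay":
        """Check invariants; in permissive mode clamp out-of-range minute totals.

        Returns a (possibly corrected) copy. Raises ValidationError in strict
        mode for any violation.
        """
        if self.missing:
            return self
        if self.day_index < 0:
            raise ValidationError(f"day_index must be >= 0, got {self.day_index}")
        for name, v in (("bedtime", self.bedtime), ("waketime", self.waketime)):
            if not (12.0 <= v < 36.0):
                raise ValidationError(
                    f"{name}={v} outside the noon-to-noon axis [12, 36)"
                )
        if min(self.n_awakenings, self.awake_min, self.n_naps, self.nap_min) < 0:
            raise ValidationError("counts and minute totals must be non-negative")
        dur = self.sleep_period_hours()
        if not (0.0 < dur < 24.0):
            raise ValidationError(
                f"sleep period of {dur:.2f} h (bed {self.bedtime}, wake "
                f"{self.waketime}) must lie in (0, 24)"
            )
        day = self
        if self.awake_min > 60.0 * dur:
            if strict:
                raise ValidationError(
                    f"awake_min={self.awake_min} exceeds the {dur:.2f} h sleep period"
                )
            warnings.warn("clamping awake_min to the sleep-period length")
            day = replace(day, awake_min=60.0 * dur)
        if self.nap_min > 60.0 * (24.0 - dur):
            if strict:
                raise ValidationError(
                    f"nap_min={self.nap_min} exceeds the {24 - dur:.2f} h wake period"
                )
            warnings.warn("clamping nap_min to the wake-period length")
            day = replace(day, nap_min=60.0 * (24.0 - dur))
        return day

    def waketime_abs(self) -> float:
        """Waketime on the same absolute axis as bedtime (adds 24 h if needed)."""
        return self.waketime if self.waketime > self.bedtime else self.waketime + 24.0

    def sleep_period_hours(self) -> float:
        """Bed-to-rise interval in hours."""
        return self.waketime_abs() - self.bedtime


@dataclass
class Diary:
    """A participant's ordered day sequence with explicit missing entries."""

    participant_id: str
    days: list[DiaryDay] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, d in enumerate(self.days):
            if d.day_index != i:
                raise ValidationError(
                    f"day_index must be contiguous from 0; position {i} has "
                    f"day_index {d.day_index}"
                )
            if d.participant_id != self.participant_id:
                raise ValidationError(
                    f"day {i} belongs to participant {d.participant_id!r}, "
                    f"not {self.participant_id!r}"
                )

    def __len__(self) -> int:
        return len(self.days)

    @property
    def n_missing(self) -> int:
        return sum(d.missing for d in self.days)

    def observed_days(self) -> list[DiaryDay]:
        return [d for d in self.days if not d.missing]


def daily_tst(day: DiaryDay) -> float:
    """Total sleep time for one night, in hours.

    Sleep-period duration minus night-awakening minutes plus nap minutes,
    clamped at 0. Raises MissingDayError for a missing day.
    """
    if day.missing:
        raise MissingDayError(
            f"participant {day.participant_id} day {day.day_index} is missing"
        )
    day = day.validate(strict=True)
    tst = day.sleep_period_hours() - day.awake_min / 60.0 + day.nap_min / 60.0
    return max(0.0, tst)


def average_tst(diary: Diary) -> float:
    """Mean daily TST over non-missing days (missing days excluded, not imputed)."""
    obs = diary.observed_days()
    if not obs:
        raise NoDataError(f"participant {diary.participant_id}: no non-missing days")
    return float(np.mean([daily_tst(d) for d in obs]))


def mean_clock_time(values: Sequence[float]) -> float:
    """Arithmetic mean of clock times on the unwrapped noon-to-noon axis."""
    if len(values) == 0:
        raise NoDataError("mean_clock_time of an empty sequence")
    arr = np.asarray(values, dtype=float)
    if np.any((arr < 12.0) | (arr >= 36.0)):
        raise ValidationError("clock times must lie on the noon-to-noon axis [12, 36)")
    return float(arr.mean())


def display_clock_time(hours: float, raw_axis: bool = False, ndigits: int = 2) -> float:
    """Display form of a noon-to-noon clock time.

    Default wraps to conventional [0, 24); ``raw_axis=True`` keeps the
    unwrapped value (useful when mirroring mixed published codings such as
    a bedtime printed 24.77 alongside one printed 01.85).
    """
    h = hours if raw_axis else hours % 24.0
    return round(h, ndigits)


def _day_from_row(row: pd.Series, strict: bool = True) -> DiaryDay:
    if bool(int(row["missing"])):
        return DiaryDay(
            participant_id=str(row["participant_id"]),
            day_index=int(row["day_index"]),
            bedtime=float("nan"),
            waketime=float("nan"),
            missing=True,
        )
    day = DiaryDay(
        participant_id=str(row["participant_id"]),
        day_index=int(row["day_index"]),
        bedtime=float(row["bedtime_h"]),
        waketime=float(row["waketime_h"]),
        n_awakenings=int(row["n_awakenings"]),
        awake_min=float(row["awake_min"]),
        n_naps=int(row["n_naps"]),
        nap_min=float(row["nap_min"]),
        missing=False,
    )
    return day.validate(strict=strict)


def read_diary_csv(path, strict: bool = True) -> dict[str, Diary]:
    """Read a long-format diary table (one row per participant-day).

    Missing days carry ``missing=1`` and empty time cells. Returns diaries
    keyed by participant id, days ordered by day_index.
    """
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    missing_cols = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"diary file lacks columns: {missing_cols}")
    if df.empty:
        raise NoDataError(f"diary file {path} contains no rows")
    diaries: dict[str, Diary] = {}
    for pid, sub in df.groupby("participant_id", sort=False):
        sub = sub.sort_values("day_index")
        days = [_day_from_row(row, strict=strict) for _, row in sub.iterrows()]
        diaries[str(pid)] = Diary(participant_id=str(pid), days=days)
    return diaries


def write_diary_csv(diaries: Iterable[Diary] | dict[str, Diary], path) -> None:
    """Write diaries in the long CSV dialect read by :func:`read_diary_csv`."""
    if isinstance(diaries, dict):
        diaries = diaries.values()
    rows = []
    for diary in diaries:
        for d in diary.days:
            if d.missing:
                rows.append(
                    {
                        "participant_id": d.participant_id,
                        "day_index": d.day_index,
                        "bedtime_h": "",
                        "waketime_h": "",
                        "n_awakenings": "",
                        "awake_min": "",
                        "n_naps": "",
                        "nap_min": "",
                        "missing": 1,
                    }
                )
            else:
                rows.append(
                    {
                        "participant_id": d.participant_id,
                        "day_index": d.day_index,
                        "bedtime_h": repr(d.bedtime),
                        "waketime_h": repr(d.waketime),
                        "n_awakenings": d.n_awakenings,
                        "awake_min": repr(d.awake_min),
                        "n_naps": d.n_naps,
                        "nap_min": repr(d.nap_min),
                        "missing": 0,
                    }
                )
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)


def participant_summary(diaries: dict[str, Diary], ndigits: int | None = 2) -> pd.DataFrame:
    """Per-participant summary table: day counts, mean TST, mean bed/wake times.

    The ``sri`` column is left NaN; the regularity module fills it in.
    Rounding to 2 dp mirrors conventional published sleep tables; pass
    ``ndigits=None`` for full precision.
    """
    rows = []
    for pid, diary in diaries.items():
        obs = diary.observed_days()
        if not obs:
            raise NoDataError(f"participant {pid}: no non-missing days")
        row = {
            "participant_id": pid,
            "n_days": len(diary),
            "n_missing": diary.n_missing,
            "mean_tst_h": average_tst(diary),
            "mean_bedtime_h": mean_clock_time([d.bedtime for d in obs]),
            "mean_waketime_h": mean_clock_time([d.waketime for d in obs]),
            "sri": float("nan"),
        }
        if ndigits is not None:
            for k in ("mean_tst_h", "mean_bedtime_h", "mean_waketime_h"):
                row[k] = round(row[k], ndigits)
        rows.append(row)
    return pd.DataFrame(rows)
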