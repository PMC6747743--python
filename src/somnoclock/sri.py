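"""Sleep Regularity Index (SRI): binary and probabilistic variants.

The SRI scores the day-to-day alignment of sleep/wake state: for every pair
of epochs 24 h apart (same epoch index on consecutive days) it asks whether
the individual was in the same state, and maps the mean agreement onto
[-100, 100], where 100 means every day is identical and 0 is chance-level
for an unstructured half-sleep schedule.

Diaries report the *number and duration* of naps and night awakenings but
not their timing, so a binary epoch state is unavailable. The probabilistic
variant therefore assigns each epoch the probability of sleep implied by the
diary totals: epochs inside the night sleep period get
``1 - awake_min / sleep_period_min`` and epochs in the wake period get
``nap_min / wake_period_min``. Pairwise agreement generalises to
``a = p1*p2 + (1-p1)*(1-p2)`` (the probability two independent epochs with
those sleep probabilities are in the same state), which reduces exactly to
the binary indicator on {0,1} grids.

Missing diary days are coded as missing; every epoch pair touching a missing
day is excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diary import Diary
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "SleepProbabilityGrid",
    "SriScore",
    "diary_to_grid",
    "sri_binary",
    "sri_probabilistic",
    "grid_to_frame",
    "grid_export",
    "grid_import",
]

MINUTES_PER_DAY = 1440


@dataclass
class SleepProbabilityGrid:
    """Days x epochs matrix of P(asleep); NaN marks missing epochs.

    Day 0, epoch 0 is anchored at study-start noon, so each row is one
    noon-to-noon window and a night's sleep never straddles rows.
    """

    participant_id: str
    epoch_min: int
    values: np.ndarray  # shape (D, M), entries in [0,1] or NaN

    def __post_init__(self) -> None:
        if MINUTES_PER_DAY % self.epoch_min != 0:
            raise ValidationError(f"epoch_min={self.epoch_min} must divide 1440")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("grid must be a 2-D days x epochs array")
        M = MINUTES_PER_DAY // self.epoch_min
        if self.values.shape[1] != M:
            raise ValidationError(
                f"grid has {self.values.shape[1]} epochs per day, expected {M}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("grid probabilities must lie in [0, 1]")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def epochs_per_day(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SriScore:
    value: float
    n_pairs_used: int
    n_pairs_total: int

    def __post_init__(self) -> None:
        if not (-100.0 - 1e-9 <= self.value <= 100.0 + 1e-9):
            raise ValidationError(f"SRI {self.value} outside [-100, 100]")
        if not (1 <= self.n_pairs_used <= self.n_pairs_total):
            raise ValidationError("need 1 <= n_pairs_used <= n_pairs_total")


def diary_to_grid(
    diary: Diary, epoch_min: int = 1, convention: str = "probabilistic"
) -> SleepProbabilityGrid:
    """Build a sleep-probability grid from a diary.

    convention
        "probabilistic" (default): epoch value = P(asleep) given diary totals,
        i.e. night epochs ``1 - awake/period`` and wake epochs ``nap/period``.
        "literal": the night-period value is instead the opposing-state
        proportion itself (``awake/period``); kept for comparison with a
        stricter word-for-word reading of the modification, under which a
        perfectly regular unbroken sleeper scores near -100 rather than 100.

    Epochs straddling the sleep-period boundary get the duration-weighted
    blend of the night and wake values.
    """
    if convention not in ("probabilistic", "literal"):
        raise ValidationError(f"unknown convention {convention!r}")
    M = MINUTES_PER_DAY // epoch_min
    grid = np.full((len(diary), M), np.nan)
    edges = np.arange(M + 1) * (epoch_min / 60.0)  # hours past noon
    for d in diary.days:
        if d.missing:
            continue
        day = d.validate(strict=True)
        dur = day.sleep_period_hours()
        sleep_start = day.bedtime - 12.0  # hours past this row's noon
        sleep_end = sleep_start + dur
        if sleep_end > 24.0 + 1e-9:
            raise ValidationError(
                f"day {day.day_index}: sleep period extends past the following "
                "noon and cannot be placed on the noon-to-noon grid"
            )
        p_night = 1.0 - day.awake_min / (60.0 * dur)
        if convention == "literal":
            p_night = day.awake_min / (60.0 * dur)
        p_wake = day.nap_min / (60.0 * (24.0 - dur))
        # overlap of each epoch [edges[j], edges[j+1]) with the sleep interval
        overlap = np.clip(
            np.minimum(edges[1:], sleep_end) - np.maximum(edges[:-1], sleep_start),
            0.0,
            None,
        )
        frac = overlap / (epoch_min / 60.0)
        grid[day.day_index] = np.clip(frac * p_night + (1.0 - frac) * p_wake, 0.0, 1.0)
    return SleepProbabilityGrid(diary.participant_id, epoch_min, grid)


def _paired(grid: SleepProbabilityGrid) -> tuple[np.ndarray, np.ndarray, int]:
    v = grid.values
    if v.shape[0] < 2:
        raise InsufficientDataError("SRI needs at least two diary days")
    a, b = v[:-1], v[1:]
    total = a.size
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise InsufficientDataError("no valid epoch pairs (both days observed)")
    return a[ok], b[ok], total


def sri_binary(grid: SleepProbabilityGrid) -> SriScore:
    """Standard SRI on a {0,1} grid: -100 + 200 * (same-state pair fraction)."""
    v = grid.values
    finite = v[np.isfinite(v)]
    if not np.isin(finite, (0.0, 1.0)).all():
        raise TypeError("sri_binary requires a {0,1} grid; use sri_probabilistic")
    p1, p2, total = _paired(grid)
    agree = float(np.mean(p1 == p2))
    return SriScore(-100.0 + 200.0 * agree, n_pairs_used=p1.size, n_pairs_total=total)


def sri_probabilistic(grid: SleepProbabilityGrid) -> SriScore:
    """Probabilistic SRI: pairwise agreement p1*p2 + (1-p1)*(1-p2).

    Equals :func:`sri_binary` exactly on binary grids.
    """
    p1, p2, total = _paired(grid)
    agree = float(np.mean(p1 * p2 + (1.0 - p1) * (1.0 - p2)))
    return SriScore(-100.0 + 200.0 * agree, n_pairs_used=p1.size, n_pairs_total=total)


def grid_to_frame(grid: SleepProbabilityGrid) -> pd.DataFrame:
    """Tidy long form: one row per (day, epoch) with P(asleep) and a missing flag."""
    D, M = grid.values.shape
    day, epoch = np.divmod(np.arange(D * M), M)
    p = grid.values.ravel()
    return pd.DataFrame(
        {
            "participant_id": grid.participant_id,
            "epoch_min": grid.epoch_min,
            "day": day,
            "epoch": epoch,
            "p_sleep": p,
            "missing": (~np.isfinite(p)).astype(int),
        }
    )


def grid_export(grid: SleepProbabilityGrid, path) -> None:
    """Write the tidy epoch grid (raster-plot data) as CSV."""
    df = grid_to_frame(grid)
    df["p_sleep"] = [repr(x) if np.isfinite(x) else "" for x in df["p_sleep"]]
    df.to_csv(path, index=False)


def grid_import(path) -> SleepProbabilityGrid:
    """Inverse of :func:`grid_export`."""
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    pid = df["participant_id"].iloc[0]
    epoch_min = int(df["epoch_min"].iloc[0])
    D = int(df["day"].max()) + 1
    M = MINUTES_PER_DAY // epoch_min
    values = np.full((D, M), np.nan)
    obs = df[df["missing"] == 0]
    values[obs["day"].to_numpy(int), obs["epoch"].to_numpy(int)] = obs[
        "p_sleep"
    ].to_numpy(float)
    return SleepProbabilityGrid(pid, epoch_min, values)
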