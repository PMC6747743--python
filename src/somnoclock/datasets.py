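"""Bundled example data.

``pilot_cohort``: a 12-participant prospective pilot cohort of first-year
university women — per-participant sleep-diary summaries (mean total sleep
time, modified Sleep Regularity Index, mean bed/wake clock times) and paired
chronological plus epigenetic ages (two clocks) at two blood draws spanning
a 9-week diary interval. Sleep-diary summaries are display-rounded to 2 dp;
bedtimes use a mixed clock coding (e.g. 24.77 vs 1.85) that the noon-to-noon
axis in :mod:`somnoclock.diary` normalises.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_pilot_sleep", "load_pilot_ages", "load_pilot_cohort"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("somnoclock.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"participant_id": str})


def load_pilot_sleep() -> pd.DataFrame:
    """Sleep table: participant_id, hispanic, sri, tst, waketime, bedtime."""
    return _read("pilot_cohort_sleep.csv")


def load_pilot_ages() -> pd.DataFrame:
    """Age table: chronological and epigenetic (horvath/grimage) ages at T1/T2."""
    return _read("pilot_cohort_ages.csv")


def load_pilot_cohort(clock: str = "horvath") -> pd.DataFrame:
    """Merged cohort table in the standard analysis schema.

    ``clock`` selects which epigenetic-age columns populate epi_t1/epi_t2.
    Row order is the published participant order.
    """
    if clock not in ("horvath", "grimage"):
        raise ValueError(f"clock must be 'horvath' or 'grimage', got {clock!r}")
    sleep = load_pilot_sleep()
    ages = load_pilot_ages()
    df = sleep.merge(ages, on="participant_id", sort=False)
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "chron_t1": df["chron_t1"],
            "chron_t2": df["chron_t2"],
            "epi_t1": df[f"{clock}_t1"],
            "epi_t2": df[f"{clock}_t2"],
            "tst": df["tst"],
            "sri": df["sri"],
        }
    )
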