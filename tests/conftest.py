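import numpy as np
import pytest

from somnoclock.datasets import load_pilot_cohort
from somnoclock.diary import Diary, DiaryDay


@pytest.fixture(scope="session")
def pilot_cohort():
    return load_pilot_cohort()


def make_day(
    pid="P1",
    idx=0,
    bed=23.0,
    wake=31.0,
    n_awk=0,
    awake_min=0.0,
    n_naps=0,
    nap_min=0.0,
    missing=False,
):
    return DiaryDay(pid, idx, bed, wake, n_awk, awake_min, n_naps, nap_min, missing)


def make_diary(day_specs, pid="P1"):
    """day_specs: list of dicts passed to make_day (day_index auto-assigned)."""
    days = [make_day(pid=pid, idx=i, **spec) for i, spec in enumerate(day_specs)]
    return Diary(pid, days)


@pytest.fixture
def regular_diary():
    return make_diary([dict(bed=23.0, wake=31.0)] * 5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
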