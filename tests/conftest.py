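from __future__ import annotations

from datetime import date, datetime

import numpy as np
import pytest

from actipat import synthetic as syn
from actipat.ingest import ActivityRecord

#: a Monday, matching the study-frame convention
MONDAY = date(2021, 11, 22)


def dt(day: date, hhmm: str) -> datetime:
    h, m = hhmm.split(":")
    return datetime(day.year, day.month, day.day, int(h), int(m))


def rec(day: date, start: str, end: str, kcal: float, pid: str = "P1") -> ActivityRecord:
    return ActivityRecord(pid, dt(day, start), dt(day, end), kcal, "interval_kcal")


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same reproducible stream,
    # independent of execution order
    return np.random.default_rng(20211122)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant week with both archetypes, reused across tests."""
    cfg = syn.study_frame_config(seed=5, n_participants=12, weekday_early_fraction=0.5)
    return syn.generate_cohort(cfg)
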