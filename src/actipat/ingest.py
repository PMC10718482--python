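"""Harmonize wrist-wearable energy-expenditure exports into 10-minute daily series.

Consumer wearables export activity energy expenditure (EE) in brand-specific
shapes.  Three canonical CSV dialects are supported:

``per_minute``
    one row per worn minute: ``participant_id, timestamp, kcal``
    (Samsung-style "kcal per minute during wearing" streams)
``interval_cal``
    one row per activity episode: ``participant_id, start, end, energy_cal``
    (Apple-style, energy in calories)
``interval_kcal``
    as above but ``energy_kcal`` (Xiaomi-style)

All dialects are normalised to :class:`ActivityRecord` (energy always in kcal)
and binned into :class:`DaySeries` — 144 clock-aligned ten-minute bins per
calendar day, each holding the kcal expended during that bin.  A record's
energy is spread at a uniform rate over its interval and apportioned to bins
by overlap, so total energy is conserved exactly.  Bins never covered by any
record are zero: non-wear is treated as zero expenditure, not as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: number of ten-minute bins in a day
N_BINS = 144
#: bin width in minutes
BIN_MINUTES = 10
MINUTES_PER_DAY = N_BINS * BIN_MINUTES

DIALECTS = ("per_minute", "interval_cal", "interval_kcal")


@dataclass(frozen=True)
class ActivityRecord:
    """One device-reported measurement: an interval and its energy in kcal."""

    participant_id: str
    start: datetime
    end: datetime
    energy: float
    dialect: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"record end {self.end} precedes start {self.start}")
        if self.energy < 0:
            raise ValueError(f"negative energy {self.energy}")


@dataclass
class DaySeries:
    """One participant-day as 144 ten-minute kcal bins.

    ``bins[i]`` covers minutes ``[10*i, 10*(i+1))`` after local midnight,
    so bin 36 starts at 06:00.  ``wear_minutes`` counts minutes covered by
    at least one record, regardless of energy.
    """

    participant_id: str
    date: Date
    bins: np.ndarray
    wear_minutes: int = 0

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.bins.shape}")
        if (self.bins < 0).any():
            raise ValueError("negative bin value")

    @property
    def total_kcal(self) -> float:
        return float(self.bins.sum())


def bin_of(t: time) -> int:
    """Bin index containing clock time ``t`` (bin_of(06:00) == 36)."""
    return (t.hour * 60 + t.minute) // BIN_MINUTES


def time_of(bin_index: int) -> time:
    """Clock time at which ``bin_index`` starts (time_of(0) == 00:00)."""
    if not 0 <= bin_index < N_BINS:
        raise ValueError(f"bin index {bin_index} out of range")
    minutes = bin_index * BIN_MINUTES
    return time(minutes // 60, minutes % 60)


# ---------------------------------------------------------------------------
# reading the dialects
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {
    "per_minute": ["participant_id", "timestamp", "kcal"],
    "interval_cal": ["participant_id", "start", "end", "energy_cal"],
    "interval_kcal": ["participant_id", "start", "end", "energy_kcal"],
}


def read_export(
    path: str | Path,
    dialect: str,
    report: dict | None = None,
) -> list[ActivityRecord]:
    """Read one export file, returning unit-normalised records in row order.

    Rows with malformed timestamps or negative energy are rejected with a
    logged warning; if ``report`` (a dict) is supplied it accumulates
    ``rows_read``, ``rows_rejected`` and ``records`` counts per file.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in _DIALECT_COLUMNS[dialect] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing} for dialect {dialect}")

    if dialect == "per_minute":
        start = pd.to_datetime(df["timestamp"], errors="coerce")
        end = start + pd.Timedelta(minutes=1)
        energy = pd.to_numeric(df["kcal"], errors="coerce")
    else:
        start = pd.to_datetime(df["start"], errors="coerce")
        end = pd.to_datetime(df["end"], errors="coerce")
        col = "energy_cal" if dialect == "interval_cal" else "energy_kcal"
        energy = pd.to_numeric(df[col], errors="coerce")
        if dialect == "interval_cal":
            energy = energy / 1000.0  # cal -> kcal

    bad = start.isna() | end.isna() | energy.isna() | (energy < 0) | (end < start)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: rejected %d malformed row(s)", path.name, n_bad)

    records = [
        ActivityRecord(pid, s.to_pydatetime(), e.to_pydatetime(), float(v), dialect)
        for pid, s, e, v in zip(
            df.loc[~bad, "participant_id"],
            start[~bad],
            end[~bad],
            energy[~bad],
        )
    ]
    if report is not None:
        report.setdefault("files", {})[path.name] = {
            "dialect": dialect,
            "rows_read": int(len(df)),
            "rows_rejected": n_bad,
            "records": len(records),
        }
    return records


def write_export(records: list[ActivityRecord], path: str | Path, dialect: str) -> None:
    """Write records as one of the CSV dialects (inverse of :func:`read_export`)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    fmt = "%Y-%m-%dT%H:%M"
    if dialect == "per_minute":
        rows = {
            "participant_id": [r.participant_id for r in records],
            "timestamp": [r.start.strftime(fmt) for r in records],
            "kcal": [r.energy for r in records],
        }
    else:
        col = "energy_cal" if dialect == "interval_cal" else "energy_kcal"
        scale = 1000.0 if dialect == "interval_cal" else 1.0
        rows = {
            "participant_id": [r.participant_id for r in records],
            "start": [r.start.strftime(fmt) for r in records],
            "end": [r.end.strftime(fmt) for r in records],
            col: [r.energy * scale for r in records],
        }
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_records(records: list[ActivityRecord], date: Date) -> DaySeries:
    """Apportion record energy into the 144 ten-minute bins of ``date``.

    Each record's energy is spread at a uniform rate over its interval; the
    part overlapping ``date`` is allocated to clock bins proportionally to
    overlap, so records straddling midnight or a bin edge are split exactly.
    A zero-duration record contributes its full energy to the bin containing
    its start.  Wear minutes are the union of minutes covered by any record.
    """
    pids = {r.participant_id for r in records}
    if len(pids) > 1:
        raise ValueError(f"records from multiple participants: {sorted(pids)}")
    participant_id = next(iter(pids)) if pids else ""

    day_start = datetime.combine(date, time.min)
    edges = np.arange(N_BINS + 1, dtype=float) * BIN_MINUTES
    bins = np.zeros(N_BINS)
    worn = np.zeros(MINUTES_PER_DAY, dtype=bool)

    for rec in records:
        s = (rec.start - day_start).total_seconds() / 60.0
        e = (rec.end - day_start).total_seconds() / 60.0
        if e < 0 or s >= MINUTES_PER_DAY:
            continue
        duration = (rec.end - rec.start).total_seconds() / 60.0
        if duration == 0.0:
            if 0 <= s < MINUTES_PER_DAY:
                bins[int(s // BIN_MINUTES)] += rec.energy
                worn[int(s)] = True
            continue
        lo, hi = max(s, 0.0), min(e, float(MINUTES_PER_DAY))
        if hi <= lo:
            continue
        rate = rec.energy / duration  # kcal per minute, uniform over the record
        overlap = np.clip(np.minimum(e, edges[1:]) - np.maximum(s, edges[:-1]), 0.0, None)
        bins += rate * overlap
        worn[int(np.floor(lo)) : int(np.ceil(hi))] = True

    return DaySeries(participant_id, date, bins, wear_minutes=int(worn.sum()))


def day_series_for(records: list[ActivityRecord]) -> dict[Date, DaySeries]:
    """Build one DaySeries per calendar date touched by the records."""
    dates: set[Date] = set()
    for r in records:
        d = r.start.date()
        stop = r.end.date()
        while d <= stop:
            dates.add(d)
            d += timedelta(days=1)
        # a record ending exactly at midnight does not touch the next day
        if r.end.time() == time.min and r.end.date() > r.start.date():
            dates.discard(r.end.date())
    return {d: bin_records(records, d) for d in sorted(dates)}


def wear_qc(day: DaySeries, threshold_hours: float = 10.0) -> bool:
    """True iff the day meets the wear-time instruction (default >= 10 h).

    This is a QC flag only; days are not excluded on it.
    """
    if threshold_hours < 0:
        raise ValueError("threshold must be non-negative")
    return day.wear_minutes >= threshold_hours * 60


def days_to_frame(days: list[DaySeries]) -> pd.DataFrame:
    """Long-format table of binned days: participant_id, date, bin, kcal."""
    return pd.DataFrame(
        {
            "participant_id": np.repeat([d.participant_id for d in days], N_BINS),
            "date": np.repeat([d.date.isoformat() for d in days], N_BINS),
            "bin": np.tile(np.arange(N_BINS), len(days)),
            "kcal": np.concatenate([d.bins for d in days]) if days else np.array([]),
        }
    )
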