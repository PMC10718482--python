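"""Per-participant weekday/weekend average daily profiles and EE totals.

Days are partitioned by calendar weekday (Monday–Friday vs Saturday–Sunday)
and, within each segment, a participant's mean daily profile is the per-bin
arithmetic mean over their contributing person-days.  Participants with no
days in a segment are excluded from that segment (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import N_BINS, DaySeries

logger = logging.getLogger(__name__)

SEGMENTS = ("weekday", "weekend")


@dataclass
class AverageSeries:
    """Mean daily 144-bin profile of one participant over one segment."""

    participant_id: str
    segment: str
    values: np.ndarray
    n_days: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} values")
        if self.n_days < 1:
            raise ValueError("an average needs at least one day")


def segment_of(day: DaySeries) -> str:
    """weekday for Monday–Friday, weekend for Saturday–Sunday."""
    return "weekday" if day.date.weekday() < 5 else "weekend"


def split_segments(days: list[DaySeries]) -> tuple[list[DaySeries], list[DaySeries]]:
    """Exhaustive, disjoint split into (weekday days, weekend days)."""
    weekday = [d for d in days if segment_of(d) == "weekday"]
    weekend = [d for d in days if segment_of(d) == "weekend"]
    return weekday, weekend


def average_series(days: list[DaySeries]) -> AverageSeries:
    """Per-bin mean profile over one participant's days in one segment."""
    if not days:
        raise ValueError("cannot average an empty set of days")
    pids = {d.participant_id for d in days}
    if len(pids) > 1:
        raise ValueError(f"days from multiple participants: {sorted(pids)}")
    segs = {segment_of(d) for d in days}
    if len(segs) > 1:
        raise ValueError("days span both segments; split first")
    values = np.mean([d.bins for d in days], axis=0)
    return AverageSeries(days[0].participant_id, segs.pop(), values, n_days=len(days))


def build_average_series(days: list[DaySeries]) -> dict[str, list[AverageSeries]]:
    """Average profiles per participant for each segment.

    Returns ``{"weekday": [...], "weekend": [...]}``, each list sorted by
    participant id.  Participants missing a segment entirely are excluded
    from that segment with a logged notice.
    """
    out: dict[str, list[AverageSeries]] = {}
    pids = sorted({d.participant_id for d in days})
    for segment, seg_days in zip(SEGMENTS, split_segments(days)):
        by_pid: dict[str, list[DaySeries]] = {}
        for d in seg_days:
            by_pid.setdefault(d.participant_id, []).append(d)
        missing = [p for p in pids if p not in by_pid]
        if missing:
            logger.info("%s: no days for participant(s) %s; excluded", segment, missing)
        out[segment] = [average_series(by_pid[p]) for p in sorted(by_pid)]
    return out


def daily_ee(day: DaySeries) -> float:
    """Total kcal for one person-day."""
    return float(day.bins.sum())


def segment_mean_ee(days: list[DaySeries]) -> float:
    """Mean of daily totals over one participant's days in one segment."""
    if not days:
        raise ValueError("no days")
    return float(np.mean([daily_ee(d) for d in days]))


def daily_ee_table(days: list[DaySeries]) -> pd.DataFrame:
    """Per participant × segment mean daily EE (kcal), wide format."""
    rows = [
        {
            "participant_id": d.participant_id,
            "segment": segment_of(d),
            "kcal": daily_ee(d),
        }
        for d in days
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["participant_id", "segment"])["kcal"]
        .mean()
        .unstack("segment")
        .rename_axis(columns=None)
    )


def average_series_frame(avg: dict[str, list[AverageSeries]]) -> pd.DataFrame:
    """Long-format export: participant_id, segment, bin, kcal."""
    frames = []
    for segment, series_list in avg.items():
        for s in series_list:
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": s.participant_id,
                        "segment": segment,
                        "bin": np.arange(N_BINS),
                        "kcal": s.values,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "segment", "bin", "kcal"]
    )
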