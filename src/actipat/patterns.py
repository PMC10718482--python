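"""Chronotype labels (early bird / night owl) and weekly pattern groups.

A participant's activity onset is the first ten-minute bin of their average
daily profile with energy expenditure above a threshold (default: any
positive EE).  Onset before 06:00 (bin 36) marks a night owl; onset at or
after 06:00 marks an early bird.  Clusters are labelled by majority vote of
their members' onsets (medoid-onset labelling available as an alternative),
and participants whose weekday and weekend labels agree form the *stable*
group while the rest form the *shifting* group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import AverageSeries
from .tsclust import ClusterModel

logger = logging.getLogger(__name__)

EARLY_BIRD = "early_bird"
NIGHT_OWL = "night_owl"
#: first bin at or after 06:00
SIX_AM_BIN = 36


@dataclass
class PatternAssignment:
    participant_id: str
    weekday_label: str
    weekend_label: str

    @property
    def group(self) -> str:
        return "stable" if self.weekday_label == self.weekend_label else "shifting"


def activity_onset(series: AverageSeries | np.ndarray, eps: float = 0.0) -> int | None:
    """Smallest bin index with value > eps; None if the profile never exceeds it."""
    values = series.values if isinstance(series, AverageSeries) else np.asarray(series)
    active = np.flatnonzero(values > eps)
    return int(active[0]) if active.size else None


def onset_label(onset: int) -> str:
    """night_owl for onsets strictly before 06:00, early_bird otherwise."""
    return NIGHT_OWL if onset < SIX_AM_BIN else EARLY_BIRD


def label_cluster(
    model: ClusterModel,
    members: list[AverageSeries],
    eps: float = 0.0,
    method: str = "majority",
) -> tuple[dict[int, str], pd.DataFrame]:
    """Label each cluster early_bird or night_owl.

    With ``method="majority"`` every member with a defined onset votes by its
    own onset (ties go to early_bird); ``method="medoid"`` uses the medoid's
    onset alone.  Members with all-zero profiles have no onset and are
    excluded from the vote with a warning.  Returns the label per cluster id
    and a per-member onset log.
    """
    if len(members) != model.assignment.size:
        raise ValueError("one series per clustered participant is required")
    rows = []
    for idx, s in enumerate(members):
        onset = activity_onset(s, eps)
        if onset is None:
            logger.warning("participant %s: all-zero profile, no onset", s.participant_id)
        rows.append(
            {
                "participant_id": s.participant_id,
                "cluster": int(model.assignment[idx]),
                "onset_bin": onset,
                "vote": None if onset is None else onset_label(onset),
            }
        )
    log = pd.DataFrame(rows)

    labels: dict[int, str] = {}
    for cid in range(model.k):
        if method == "medoid":
            onset = activity_onset(members[model.medoids[cid]], eps)
            if onset is None:
                raise ValueError(f"cluster {cid}: medoid has no defined onset")
            labels[cid] = onset_label(onset)
            continue
        votes = log.loc[(log["cluster"] == cid) & log["vote"].notna(), "vote"]
        if votes.empty:
            raise ValueError(f"cluster {cid}: no member has a defined onset")
        n_night = int((votes == NIGHT_OWL).sum())
        # strict majority required for night_owl; ties resolve to early_bird
        labels[cid] = NIGHT_OWL if n_night > len(votes) - n_night else EARLY_BIRD
    return labels, log


def assign_group(weekday_label: str, weekend_label: str) -> str:
    """stable iff the weekday and weekend labels agree."""
    for lab in (weekday_label, weekend_label):
        if lab not in (EARLY_BIRD, NIGHT_OWL):
            raise ValueError(f"unknown label {lab!r}")
    return "stable" if weekday_label == weekend_label else "shifting"


def pattern_table(
    weekday_model: ClusterModel,
    weekday_members: list[AverageSeries],
    weekend_model: ClusterModel,
    weekend_members: list[AverageSeries],
    eps: float = 0.0,
    method: str = "majority",
) -> pd.DataFrame:
    """Join segment labellings into the per-participant pattern table.

    Participants present in only one segment get no group (excluded, logged).
    Columns: participant_id, weekday_cluster, weekend_cluster, weekday_label,
    weekend_label, group.
    """
    frames = {}
    for seg, model, members in (
        ("weekday", weekday_model, weekday_members),
        ("weekend", weekend_model, weekend_members),
    ):
        labels, log = label_cluster(model, members, eps=eps, method=method)
        log[f"{seg}_label"] = log["cluster"].map(labels)
        frames[seg] = log.rename(columns={"cluster": f"{seg}_cluster"})[
            ["participant_id", f"{seg}_cluster", f"{seg}_label"]
        ]
    merged = frames["weekday"].merge(frames["weekend"], on="participant_id", how="outer")
    incomplete = merged["weekday_label"].isna() | merged["weekend_label"].isna()
    if incomplete.any():
        logger.info(
            "no group for participant(s) missing a segment: %s",
            merged.loc[incomplete, "participant_id"].tolist(),
        )
    merged["group"] = np.where(
        incomplete,
        None,
        np.where(merged["weekday_label"] == merged["weekend_label"], "stable", "shifting"),
    )
    return merged.sort_values("participant_id", ignore_index=True)
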