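"""Synthetic wearable cohorts with known chronotype ground truth.

Emulates the study frame of a one-week wrist-wearable cohort: each
participant carries a diurnal archetype per segment — *early bird* (first
activity at or after 06:00) or *night owl* (first activity before 06:00) —
plus binary covariates (sex, age group, work type, metabolic risk-factor
count).  A participant is *shifting* when the weekend archetype flips from
the weekday one, optionally with age-dependent log-odds so covariate-effect
recovery can be tested against a configured truth.

Days are rendered on a minute grid: activity bouts start at a truncated-
normal onset (truncation at the 06:00 boundary keeps the archetype
constraint exact), are short on weekdays and long on weekends, expend
energy at ~1 kcal/min with lognormal jitter, and non-wear gaps are placed
outside bouts.  Each participant exports in one of the three device
dialects.  Ground-truth 10-minute bin series are accumulated directly on
the minute grid — an arithmetic route independent of the ingest module's
interval-overlap apportionment, which makes round-trip checks meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ActivityRecord, BIN_MINUTES, MINUTES_PER_DAY, N_BINS, write_export

EARLY, NIGHT = "early_bird", "night_owl"
SIX_AM_MIN = 360  # minutes after midnight


@dataclass
class CohortConfig:
    """Study-frame and behaviour parameters for one synthetic cohort.

    Defaults emulate the reference frame: 47 participants, 7 consecutive
    days from a Monday, ~80% weekday early birds, ~25% shifting, onsets
    drawn around 08:00 (early) and 04:00 (night) with SD 60 min truncated at
    the 06:00 boundary, short weekday bouts vs long weekend bouts, and
    energy rates that put recorded daily totals in the 150-400 kcal range.
    """

    n_participants: int = 47
    start_date: Date = Date(2021, 11, 22)  # a Monday
    n_days: int = 7

    # archetypes and grouping
    weekday_early_fraction: float = 0.8
    shifting_fraction: float = 0.25
    age_shift_log_odds: float = 0.0  # added to the shifting logit for age >= 40

    # onset model (minutes after midnight)
    early_onset_mean: float = 480.0  # 08:00
    night_onset_mean: float = 240.0  # 04:00
    onset_sd: float = 60.0
    early_end_mean: float = 1200.0  # 20:00
    night_end_mean: float = 960.0  # 16:00
    end_sd: float = 60.0

    # bout model
    weekday_bouts_mean: float = 5.0
    weekend_bouts_mean: float = 2.0
    weekday_bout_minutes: float = 20.0
    weekend_bout_minutes: float = 80.0
    early_kcal_per_min: float = 0.9
    night_kcal_per_min: float = 1.4
    rate_sigma: float = 0.3  # lognormal jitter on the per-bout rate

    # wear model
    n_gaps: int = 2
    gap_minutes: tuple[int, int] = (30, 120)

    # covariates
    p_male: float = 0.49
    p_age_ge40: float = 0.36
    p_sitting: float = 0.89
    p_multi_risk: float = 0.47

    dialect_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # per_minute, cal, kcal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0 <= self.weekday_early_fraction <= 1:
            raise ValueError("weekday_early_fraction must be in [0, 1]")
        if not 0 <= self.shifting_fraction <= 1:
            raise ValueError("shifting_fraction must be in [0, 1]")
        if abs(sum(self.dialect_mix) - 1) > 1e-9:
            raise ValueError("dialect_mix must sum to 1")
        if self.weekday_bout_minutes >= MINUTES_PER_DAY or self.weekend_bout_minutes >= MINUTES_PER_DAY:
            raise ValueError("bout length exceeds a day")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    config: CohortConfig
    participants: pd.DataFrame  # one row per participant
    bins: dict[tuple[str, Date], np.ndarray]  # true 144-bin kcal series
    records: dict[str, list[ActivityRecord]]

    @property
    def person_days(self) -> int:
        return len(self.bins)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v < hi:
            return v
    return float(np.clip(mean, lo, hi - 1))


def generate_covariates(config: CohortConfig, n: int | None = None) -> pd.DataFrame:
    """Draw per-participant covariates, archetypes and the shifting group.

    The shifting indicator follows logit(p) = logit(shifting_fraction) +
    beta * (age_ge40 - P(age_ge40)), centred so the marginal shifting rate
    stays near the configured fraction for any beta.
    """
    n = config.n_participants if n is None else n
    rng = np.random.default_rng([config.seed, 2**20])
    ids = [f"P{i:04d}" for i in range(n)]
    male = rng.random(n) < config.p_male
    age40 = rng.random(n) < config.p_age_ge40
    sitting = rng.random(n) < config.p_sitting
    multi = rng.random(n) < config.p_multi_risk

    frac = min(max(config.shifting_fraction, 1e-9), 1 - 1e-9)
    base = np.log(frac / (1 - frac))
    eta = base + config.age_shift_log_odds * (age40.astype(float) - config.p_age_ge40)
    shifting = rng.random(n) < 1 / (1 + np.exp(-eta))

    wk_early = rng.random(n) < config.weekday_early_fraction
    weekday_archetype = np.where(wk_early, EARLY, NIGHT)
    weekend_archetype = np.where(
        shifting,
        np.where(wk_early, NIGHT, EARLY),
        weekday_archetype,
    )
    return pd.DataFrame(
        {
            "participant_id": ids,
            "male": male.astype(int),
            "female": (~male).astype(int),
            "age_ge40": age40.astype(int),
            "sitting": sitting.astype(int),
            "multi_risk": multi.astype(int),
            "weekday_archetype": weekday_archetype,
            "weekend_archetype": weekend_archetype,
            "group": np.where(shifting, "shifting", "stable"),
            "dialect": [
                ("per_minute", "interval_cal", "interval_kcal")[d]
                for d in rng.choice(3, size=n, p=list(config.dialect_mix))
            ],
        }
    )


def _simulate_day(
    rng: np.random.Generator, config: CohortConfig, archetype: str, is_weekend: bool
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, float]]]:
    """One day on the minute grid.

    Returns (kcal-per-minute array, worn mask, bouts as (start, end, kcal)).
    The first bout starts exactly at the drawn onset, so the first active
    minute respects the archetype's 06:00 boundary by construction.
    """
    if archetype == EARLY:
        onset = _truncnorm(rng, config.early_onset_mean, config.onset_sd, SIX_AM_MIN, MINUTES_PER_DAY - 60)
        end = _truncnorm(rng, config.early_end_mean, config.end_sd, onset + 30, MINUTES_PER_DAY)
        base_rate = config.early_kcal_per_min
    else:
        onset = _truncnorm(rng, config.night_onset_mean, config.onset_sd, 0, SIX_AM_MIN)
        end = _truncnorm(rng, config.night_end_mean, config.end_sd, onset + 30, MINUTES_PER_DAY)
        base_rate = config.night_kcal_per_min

    bouts_mean = config.weekend_bouts_mean if is_weekend else config.weekday_bouts_mean
    bout_len = config.weekend_bout_minutes if is_weekend else config.weekday_bout_minutes
    n_bouts = int(rng.poisson(max(bouts_mean - 1, 0.0))) + 1 if bouts_mean > 0 else 0

    rate = np.zeros(MINUTES_PER_DAY)
    bouts: list[tuple[int, int, float]] = []
    for b in range(n_bouts):
        start = int(onset) if b == 0 else int(rng.uniform(onset, max(end - 1, onset + 1)))
        length = max(10, int(rng.lognormal(np.log(bout_len), 0.3)))
        # snap to the 10-minute grid so interval exports rebin exactly
        start = (start // BIN_MINUTES) * BIN_MINUTES if b > 0 else start
        stop = min(start + length, MINUTES_PER_DAY)
        r = base_rate * rng.lognormal(0.0, config.rate_sigma)
        rate[start:stop] += r
        bouts.append((start, stop, r * (stop - start)))

    worn = np.ones(MINUTES_PER_DAY, dtype=bool)
    active = rate > 0
    for _ in range(config.n_gaps):
        glen = int(rng.integers(config.gap_minutes[0], config.gap_minutes[1] + 1))
        for _ in range(50):  # place the gap away from activity
            gstart = int(rng.integers(0, MINUTES_PER_DAY - glen))
            if not active[gstart : gstart + glen].any():
                worn[gstart : gstart + glen] = False
                break
    return rate, worn, bouts


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> GroundTruth:
    """Generate the cohort; optionally write export files and ground truth.

    Deterministic for a fixed config (per-participant random substreams are
    derived from the seed, so the same seed yields byte-identical exports).
    When ``out_dir`` is given, one CSV per participant is written in their
    dialect plus ``attributes.csv`` and ``truth_bins.csv``.
    """
    participants = generate_covariates(config)
    bins: dict[tuple[str, Date], np.ndarray] = {}
    records: dict[str, list[ActivityRecord]] = {}

    for idx, row in participants.iterrows():
        rng = np.random.default_rng([config.seed, int(idx)])
        pid = row["participant_id"]
        recs: list[ActivityRecord] = []
        for d in range(config.n_days):
            day = config.start_date + timedelta(days=d)
            is_weekend = day.weekday() >= 5
            archetype = row["weekend_archetype"] if is_weekend else row["weekday_archetype"]
            rate, worn, bouts = _simulate_day(rng, config, archetype, is_weekend)
            bins[(pid, day)] = rate.reshape(N_BINS, BIN_MINUTES).sum(axis=1)
            midnight = datetime.combine(day, time.min)
            if row["dialect"] == "per_minute":
                for m in np.flatnonzero(worn):
                    recs.append(
                        ActivityRecord(
                            pid,
                            midnight + timedelta(minutes=int(m)),
                            midnight + timedelta(minutes=int(m) + 1),
                            float(rate[m]),
                            "per_minute",
                        )
                    )
            else:
                for start, stop, kcal in bouts:
                    recs.append(
                        ActivityRecord(
                            pid,
                            midnight + timedelta(minutes=start),
                            midnight + timedelta(minutes=stop),
                            float(kcal),
                            row["dialect"],
                        )
                    )
        records[pid] = recs

    truth = GroundTruth(config=config, participants=participants, bins=bins, records=records)
    if out_dir is not None:
        write_cohort(truth, out_dir)
    return truth


def write_cohort(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for _, row in truth.participants.iterrows():
        pid = row["participant_id"]
        write_export(truth.records[pid], out / f"{pid}.csv", row["dialect"])
    covariate_cols = [
        "participant_id", "male", "female", "age_ge40", "sitting", "multi_risk", "dialect",
    ]
    truth.participants[covariate_cols].to_csv(out / "attributes.csv", index=False)
    truth.participants.to_csv(out / "truth_participants.csv", index=False)
    pd.DataFrame(
        {
            "participant_id": np.repeat([k[0] for k in truth.bins], N_BINS),
            "date": np.repeat([k[1].isoformat() for k in truth.bins], N_BINS),
            "bin": np.tile(np.arange(N_BINS), len(truth.bins)),
            "kcal": np.concatenate(list(truth.bins.values())) if truth.bins else np.array([]),
        }
    ).to_csv(out / "truth_bins.csv", index=False)


def study_frame_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study frame (47 x 7 from a Monday) with overrides."""
    return replace(CohortConfig(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

def _best_label_agreement(true_labels: np.ndarray, clusters: np.ndarray) -> float:
    """Cluster-archetype agreement under the best cluster->archetype map."""
    best = 0
    archetypes = np.unique(true_labels)
    cluster_ids = np.unique(clusters)
    # map each cluster independently to its majority archetype
    matched = 0
    for cid in cluster_ids:
        member_truth = true_labels[clusters == cid]
        matched += max((member_truth == a).sum() for a in archetypes)
    best = matched / len(true_labels)
    return float(best)


def recovery_report(truth: GroundTruth, pattern_table: pd.DataFrame) -> dict:
    """Agreement between generator truth and pipeline output.

    ``pattern_table`` is the patterns module output (participant_id,
    weekday_cluster, weekend_cluster, weekday_label, weekend_label, group).
    """
    merged = truth.participants.merge(pattern_table, on="participant_id", how="inner", suffixes=("_true", ""))
    if len(merged) != len(truth.participants):
        raise ValueError("participant sets differ between truth and pipeline output")
    out: dict = {}
    for seg in ("weekday", "weekend"):
        out[f"{seg}_cluster_agreement"] = _best_label_agreement(
            merged[f"{seg}_archetype"].to_numpy(), merged[f"{seg}_cluster"].to_numpy()
        )
        out[f"{seg}_label_accuracy"] = float(
            (merged[f"{seg}_archetype"] == merged[f"{seg}_label"]).mean()
        )
    out["group_accuracy"] = float((merged["group_true"] == merged["group"]).mean())
    return out
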