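"""End-to-end orchestration: ingest -> series -> cluster -> label -> stats.

A run consumes a directory of device export files (one CSV per participant,
any mix of the three dialects declared in an ``attributes.csv`` table) or
generates one synthetically, then executes the analysis stages in order,
writing each stage's tables plus a run manifest.  Weekday and weekend
clustering run independently.  The pipeline is deterministic: all
randomness lives in the synthetic generator's seed, and every later stage
is seed-free, so identical inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ingest as ing
from . import series as ser
from . import stats as st
from . import synthetic as syn
from .patterns import pattern_table
from .tsclust import select_model

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "simulate": None,  # or a dict of CohortConfig overrides incl. seed
    "ingest": {"wear_threshold_hours": 10.0},
    "cluster": {"window": 14, "k_grid": [2, 3, 4, 5, 6], "cutoff_grid": None},
    "patterns": {"eps": 0.0, "label_method": "majority"},
}


def load_config(path: str | Path | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        try:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        for key, val in user.items():
            if key not in cfg:
                raise ConfigError(f"unknown config section {key!r}")
            if isinstance(cfg[key], dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def ingest_stage(data_dir: Path, wear_threshold_hours: float = 10.0):
    """Read all exports into per-participant day series.

    Requires ``attributes.csv`` with participant_id and dialect columns.
    Returns (days, attributes, ingest report).
    """
    attr_path = data_dir / "attributes.csv"
    if not attr_path.exists():
        raise DataError(f"missing {attr_path}")
    attrs = pd.read_csv(attr_path, dtype={"participant_id": str})
    report: dict = {}
    days: list[ing.DaySeries] = []
    qc: dict[str, int] = {"days_total": 0, "days_below_wear_threshold": 0}
    for _, row in attrs.iterrows():
        pid, dialect = row["participant_id"], row["dialect"]
        path = data_dir / f"{pid}.csv"
        if not path.exists():
            raise DataError(f"missing export file for participant {pid}")
        recs = ing.read_export(path, dialect, report=report)
        for day in ing.day_series_for(recs).values():
            qc["days_total"] += 1
            if not ing.wear_qc(day, wear_threshold_hours):
                qc["days_below_wear_threshold"] += 1
            days.append(day)
    report["wear_qc"] = qc
    return days, attrs, report


def run_all(
    config: dict | str | Path | None,
    out_dir: str | Path,
    data_dir: str | Path | None = None,
) -> dict:
    """Run every stage; return the finalized manifest (also written to disk).

    ``data_dir`` holds existing exports; when absent, the ``simulate``
    config section must be present to generate a cohort first.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(cfg), "stages": {}, "status": "running"}
    _write_manifest(out, manifest)

    try:
        # --- simulate (optional) ---
        if data_dir is None:
            sim = cfg.get("simulate")
            if sim is None:
                raise ConfigError("no data_dir given and no simulate section in config")
            t0 = _time.perf_counter()
            truth = syn.generate_cohort(syn.study_frame_config(**sim), out / "cohort")
            data_dir = out / "cohort"
            manifest["stages"]["simulate"] = {
                "seconds": round(_time.perf_counter() - t0, 3),
                "participants": int(len(truth.participants)),
                "person_days": truth.person_days,
            }
        data_dir = Path(data_dir)
        manifest["inputs"] = {
            p.name: _checksum(p) for p in sorted(data_dir.glob("*.csv"))
        }

        # --- ingest ---
        t0 = _time.perf_counter()
        days, attrs, report = ingest_stage(
            data_dir, cfg["ingest"]["wear_threshold_hours"]
        )
        ing.days_to_frame(days).to_csv(out / "day_series.csv", index=False)
        (out / "ingest_report.json").write_text(json.dumps(report, indent=2))
        weekday_days, weekend_days = ser.split_segments(days)
        manifest["stages"]["ingest"] = {
            "seconds": round(_time.perf_counter() - t0, 3),
            "participants": int(attrs["participant_id"].nunique()),
            "person_days": len(days),
            "weekday_person_days": len(weekday_days),
            "weekend_person_days": len(weekend_days),
        }

        # --- series ---
        avg = ser.build_average_series(days)
        ser.average_series_frame(avg).to_csv(out / "average_series.csv", index=False)
        ee = ser.daily_ee_table(days)
        ee.to_csv(out / "daily_ee.csv")

        # --- cluster (weekday and weekend independently) ---
        ccfg = cfg["cluster"]
        models = {}
        t0 = _time.perf_counter()
        for segment in ser.SEGMENTS:
            if len(avg[segment]) < 2:
                raise DataError(
                    f"{segment}: fewer than 2 participants with data; cannot cluster"
                )
            X = np.vstack([s.values for s in avg[segment]])
            models[segment] = select_model(
                X,
                k_grid=ccfg["k_grid"],
                cutoff_grid=ccfg.get("cutoff_grid"),
                window=ccfg["window"],
            )
            models[segment].grid.assign(segment=segment).to_csv(
                out / f"grid_scores_{segment}.csv", index=False
            )
        manifest["stages"]["cluster"] = {
            "seconds": round(_time.perf_counter() - t0, 3),
            **{
                f"{seg}_{key}": val
                for seg, m in models.items()
                for key, val in (
                    ("k", m.k),
                    ("cutoff", round(m.cutoff, 4)),
                    ("silhouette", round(m.silhouette, 4)),
                )
            },
        }

        # --- patterns ---
        pcfg = cfg["patterns"]
        pat = pattern_table(
            models["weekday"],
            avg["weekday"],
            models["weekend"],
            avg["weekend"],
            eps=pcfg["eps"],
            method=pcfg["label_method"],
        )
        pat.to_csv(out / "patterns.csv", index=False)
        manifest["stages"]["patterns"] = {
            "stable": int((pat["group"] == "stable").sum()),
            "shifting": int((pat["group"] == "shifting").sum()),
            "ungrouped": int(pat["group"].isna().sum()),
        }

        # --- stats ---
        data = attrs.merge(pat[["participant_id", "group"]], on="participant_id")
        data = data[data["group"].notna()]
        comparison = st.group_comparison_table(data, ee)
        comparison.to_csv(out / "group_comparison.csv", index=False)
        stats_summary: dict = {}
        try:
            fit = st.pattern_association_model(data)
            fit.table().to_csv(out / "odds_ratios.csv", index=False)
            stats_summary["association"] = _jsonable(st.diagnostics(fit))
            stats_summary["association"]["separation"] = fit.separation
            rev = st.reverse_model(data)
            rev.table().to_csv(out / "reverse_odds_ratios.csv", index=False)
            stats_summary["reverse_p_shifting"] = float(
                rev.table().set_index("term").loc["shifting", "p"]
            )
        except ValueError as exc:  # e.g. one group empty in a tiny cohort
            stats_summary["association_error"] = str(exc)
        (out / "stats_summary.json").write_text(json.dumps(stats_summary, indent=2))
        manifest["stages"]["stats"] = {
            "comparison_rows": int(len(comparison)),
            **{k: v for k, v in stats_summary.items() if not isinstance(v, dict)},
        }

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
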