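"""Readers and writers for the package's file formats.

Formats:

* actigraphy CSV — header ``timestamp,activity``, ISO-8601 timestamps,
  one row per epoch, uniform epoch length; a missing epoch is either an
  empty activity field or a gap in the timestamp grid (gaps are
  materialized as missing epochs on read);
* study-table CSV — one row per study of the cross-cultural meta-table
  (sleep quotas plus covariates);
* results JSON/CSV — NPCRA results and posterior summary tables, always
  with a config echo so any output is regenerable from its file alone.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .recordings import ActigraphyRecording

__all__ = [
    "read_actigraphy_csv",
    "write_actigraphy_csv",
    "read_study_table",
    "write_study_table",
    "validate_study_table",
    "write_results_json",
]

REQUIRED_STUDY_COLUMNS = [
    "study_id",
    "country",
    "society_scale",
    "outcome_duration",
    "mean_age",
    "pct_male",
    "sample_size",
    "latitude",
    "longitude",
    "method",
]


def write_actigraphy_csv(rec: ActigraphyRecording, path: str | Path) -> None:
    """Write one recording as ``timestamp,activity`` rows (missing epochs
    get an empty activity field)."""
    times = rec.epoch_times()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "activity"])
        for t, a, m in zip(times, rec.activity, rec.missing_mask):
            w.writerow([t.isoformat(), "" if m else repr(float(a))])


def read_actigraphy_csv(path: str | Path, subject_id: str | None = None) -> ActigraphyRecording:
    """Read an actigraphy CSV, validating the dialect.

    The epoch length is inferred as the smallest timestamp step; all
    steps must be whole multiples of it (otherwise the epoch grid is
    mixed and the file is rejected). Timestamp gaps are materialized as
    missing epochs. Non-monotone timestamps or malformed rows raise with
    the offending line number.
    """
    path = Path(path)
    times: list[datetime] = []
    acts: list[float | None] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["timestamp", "activity"]:
            raise ValueError(f"{path}: expected header 'timestamp,activity'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}")
            try:
                t = datetime.fromisoformat(row[0].strip())
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: bad timestamp {row[0]!r}: {e}") from None
            raw = row[1].strip()
            if raw == "":
                a = None
            else:
                try:
                    a = float(raw)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad activity {row[1]!r}") from None
                if a < 0:
                    raise ValueError(f"{path}:{lineno}: negative activity {a}")
            times.append(t)
            acts.append(a)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two epochs")

    deltas = np.array(
        [(t2 - t1).total_seconds() for t1, t2 in zip(times, times[1:])]
    )
    if (deltas <= 0).any():
        i = int(np.flatnonzero(deltas <= 0)[0])
        raise ValueError(
            f"{path}:{i + 3}: timestamps are not strictly increasing"
        )
    epoch = float(deltas.min())
    if not epoch.is_integer():
        raise ValueError(f"{path}: sub-second epoch length {epoch}")
    steps = deltas / epoch
    if not np.allclose(steps, np.round(steps)):
        raise ValueError(
            f"{path}: mixed epoch lengths (steps are not multiples of {epoch:.0f} s)"
        )
    steps = np.round(steps).astype(int)

    activity: list[float] = []
    missing: list[bool] = []
    for i, (a, k) in enumerate(zip(acts, np.append(steps, 1))):
        activity.append(np.nan if a is None else a)
        missing.append(a is None)
        for _ in range(int(k) - 1):  # gap -> materialize missing epochs
            activity.append(np.nan)
            missing.append(True)
    act = np.asarray(activity)
    act[np.isnan(act)] = 0.0  # placeholder under the missing mask
    return ActigraphyRecording(
        subject_id=subject_id or path.stem,
        start_time=times[0],
        epoch_seconds=int(epoch),
        activity=act,
        missing_mask=np.asarray(missing, dtype=bool),
    )


def write_study_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_study_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a study-level meta-table.

    ``column_map`` maps file column names to the canonical schema (for
    deposits whose headers differ); unknown extra columns are kept as
    opaque passthrough. ``outcome_efficiency`` is optional (not every
    study reports sleep efficiency).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    for col in ("outcome_duration", "mean_age", "pct_male", "latitude", "longitude"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    dur = df["outcome_duration"]
    if ((dur <= 0) | (dur >= 24)).any():
        raise ValueError("outcome_duration must lie in (0, 24) hours")
    if "outcome_efficiency" in df.columns:
        eff = pd.to_numeric(df["outcome_efficiency"], errors="raise")
        if ((eff.dropna() <= 0) | (eff.dropna() > 100)).any():
            raise ValueError("outcome_efficiency must lie in (0, 100]")
    if (df["latitude"].abs() > 90).any():
        raise ValueError("latitude out of [-90, 90]")
    if (df["longitude"].abs() > 180).any():
        raise ValueError("longitude out of [-180, 180]")
    if ((df["pct_male"] < 0) | (df["pct_male"] > 100)).any():
        raise ValueError("pct_male out of [0, 100]")
    return df


def validate_study_table(
    df: pd.DataFrame,
    age_range: tuple[float, float] = (18.0, 75.0),
    allowed_methods: tuple[str, ...] = ("PSG", "actigraphy"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the meta-analysis inclusion criteria as row filters.

    Implementable criteria: mean age within [18, 75] and a validated
    objective measurement method (PSG or actigraphy; self-report rows are
    rejected). Health-status and baseline-only criteria are study
    metadata, passed through untouched. Returns the clean table and a
    per-row exclusion report (study_id, reason).
    """
    reasons = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.reset_index(drop=True).iterrows():
        if not age_range[0] <= float(row["mean_age"]) <= age_range[1]:
            keep[i] = False
            reasons.append({"study_id": row["study_id"], "reason": "age range"})
        elif str(row["method"]) not in allowed_methods:
            keep[i] = False
            reasons.append(
                {"study_id": row["study_id"], "reason": "measurement method"}
            )
    clean = df.reset_index(drop=True)[keep].reset_index(drop=True)
    if clean.empty:
        raise ValueError("no studies remain after applying inclusion criteria")
    report = pd.DataFrame(reasons, columns=["study_id", "reason"])
    return clean, report


def write_results_json(
    payload: dict, path: str | Path, config_echo: dict | None = None
) -> None:
    """Write a results JSON with an embedded config echo."""
    out = dict(payload)
    out["config"] = config_echo or {}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
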