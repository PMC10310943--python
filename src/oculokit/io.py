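"""Readers and writers for the on-disk formats.

Gaze CSV: ``subject_id,task,trial_id,t,x_deg,y_deg,valid`` (UTF-8, ``.``
decimal, header required). Schedule JSON: a metadata block plus one object
per trial. Parameter table CSV: ``subject_id,group,age,sex,updrs3`` followed
by the 24 canonical parameter columns.

Readers reject rather than coerce: a malformed file raises
:class:`~oculokit.types.FormatError` or :class:`~oculokit.types.DataError`
naming the problem; invalid samples are flagged, never dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_PARAMETERS,
    DataError,
    FormatError,
    GazeRecording,
    SubjectParameters,
    Task,
    Trial,
    TrialSchedule,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_schedule",
    "write_schedule",
    "read_parameter_table",
    "write_parameter_table",
]

PathLike = Union[str, Path]

GAZE_COLUMNS = ["subject_id", "task", "trial_id", "t", "x_deg", "y_deg", "valid"]
META_COLUMNS = ["subject_id", "group", "age", "sex", "updrs3"]


def read_recording(path: PathLike, sample_rate: float = 60.0) -> GazeRecording:
    """Read one gaze CSV into a :class:`GazeRecording`.

    The file must contain a single subject/task combination. Rows with
    ``valid`` equal to 0 are retained with ``valid=False``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise DataError(f"{path}: no gaze samples")
    subjects = df["subject_id"].astype(str).unique()
    tasks = df["task"].astype(str).unique()
    if len(subjects) != 1 or len(tasks) != 1:
        raise DataError(f"{path}: expected one subject/task, found {subjects}/{tasks}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) < 0)
    if bad.size:
        raise DataError(f"{path}: time not non-decreasing at row {int(bad[0]) + 1}")
    return GazeRecording(
        subject_id=str(subjects[0]),
        task=Task(tasks[0]),
        t=t,
        x=df["x_deg"].to_numpy(dtype=float),
        y=df["y_deg"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy().astype(bool),
        trial_id=df["trial_id"].to_numpy(dtype=int),
        sample_rate=sample_rate,
    )


def write_recording(recording: GazeRecording, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "subject_id": recording.subject_id,
            "task": recording.task.value,
            "trial_id": recording.trial_id,
            "t": recording.t,
            "x_deg": recording.x,
            "y_deg": recording.y,
            "valid": recording.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


_TRIAL_FIELDS = [
    "trial_id",
    "target_x",
    "target_y",
    "fixation_onset",
    "target_onset",
    "target_duration",
    "eccentricity_class",
    "arrow_direction",
    "arrow_onset",
    "arrow_duration",
    "response_window",
]


def write_schedule(schedule: TrialSchedule, path: PathLike) -> None:
    payload = {
        "task": schedule.task.value,
        "sample_rate": schedule.sample_rate,
        "trials": [
            {k: getattr(tr, k) for k in _TRIAL_FIELDS if getattr(tr, k) is not None}
            for tr in schedule.trials
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_schedule(path: PathLike) -> TrialSchedule:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("task", "trials"):
        if key not in payload:
            raise FormatError(f"{path}: missing required key '{key}'")
    trials = [Trial(**obj) for obj in payload["trials"]]
    return TrialSchedule(
        task=Task(payload["task"]),
        trials=trials,
        sample_rate=float(payload.get("sample_rate", 60.0)),
    )


def write_parameter_table(rows: Sequence[SubjectParameters], path: PathLike) -> None:
    """Write subject parameter rows as CSV (round-trips to 1e-12 relative).

    All rows must share the canonical parameter name set (enforced by
    :class:`SubjectParameters` itself); an empty sequence yields a
    header-only file.
    """
    records = []
    for row in rows:
        rec = {
            "subject_id": row.subject_id,
            "group": row.group,
            "age": row.age,
            "sex": row.sex,
            "updrs3": np.nan if row.updrs3 is None else row.updrs3,
        }
        rec.update({name: row.parameters[name] for name in CANONICAL_PARAMETERS})
        records.append(rec)
    df = pd.DataFrame(records, columns=META_COLUMNS + list(CANONICAL_PARAMETERS))
    df.to_csv(path, index=False, float_format="%.17g")


def read_parameter_table(path: PathLike) -> pd.DataFrame:
    """Read a parameter table; returns a DataFrame indexed like the file.

    Values parse with exact (round-trip) float precision so that
    write -> read -> write reproduces the file byte for byte.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS + list(CANONICAL_PARAMETERS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def parameter_rows(df: pd.DataFrame) -> list[SubjectParameters]:
    """Convert a parameter-table DataFrame back into typed rows."""
    rows = []
    for _, r in df.iterrows():
        updrs = r["updrs3"]
        rows.append(
            SubjectParameters(
                subject_id=str(r["subject_id"]),
                group=str(r["group"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                updrs3=None if pd.isna(updrs) else float(updrs),
                parameters={name: float(r[name]) for name in CANONICAL_PARAMETERS},
            )
        )
    return rows
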