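"""CSV/JSON interfaces for recordings, annotations, features, and results.

Recording files hold one device's time series with header ``t,ax,ay,az``
(plus ``gx,gy,gz`` for the hand sensor); time in seconds, acceleration in
G, angular velocity in deg/s.  A manifest CSV lists the per-recording files
with their provenance; annotations live in a single CSV with columns
``participant,task,repetition,symptom,score``.  Malformed rows are rejected
with the offending column and line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthdata import SensorRecording, SymptomAnnotation

__all__ = [
    "ParseError",
    "write_recording_csv",
    "read_recording_csv",
    "write_dataset",
    "read_dataset",
    "write_annotations",
    "read_annotations",
    "write_clip_store",
    "read_clip_store",
    "write_feature_table",
    "read_feature_table",
    "write_results_json",
]

RESULTS_SCHEMA_VERSION = 1

ACCEL_COLS = ["ax", "ay", "az"]
GYRO_COLS = ["gx", "gy", "gz"]


class ParseError(ValueError):
    """Input file violates its schema; message names column and line."""


def write_recording_csv(recording: SensorRecording, path: str | Path) -> None:
    cols = {"t": recording.timestamps}
    for name, row in zip(ACCEL_COLS, recording.accel):
        cols[name] = row
    if recording.gyro is not None:
        for name, row in zip(GYRO_COLS, recording.gyro):
            cols[name] = row
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_recording_csv(
    path: str | Path,
    device: str,
    participant_id: str,
    task_id: str,
    repetition: int,
    nominal_rate: float,
) -> SensorRecording:
    df = pd.read_csv(path)
    required = ["t", *ACCEL_COLS] + (GYRO_COLS if device == "hand_sensor" else [])
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r} required for device {device!r}")
    t = df["t"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError(
            f"{path}: column 't' not strictly increasing at line {bad[0] + 3}"
        )  # +1 header, +1 next row, 1-based
    accel = df[ACCEL_COLS].to_numpy(float).T
    gyro = df[GYRO_COLS].to_numpy(float).T if device == "hand_sensor" else None
    return SensorRecording(
        device=device,
        participant_id=participant_id,
        task_id=task_id,
        repetition=int(repetition),
        timestamps=t,
        accel=accel,
        gyro=gyro,
        nominal_rate=float(nominal_rate),
    )


def write_dataset(
    recordings: Sequence[SensorRecording],
    annotations: Sequence[SymptomAnnotation],
    out_dir: str | Path,
) -> Path:
    """Write one CSV per recording plus a manifest and the annotation table.

    Returns the manifest path.
    """
    out = Path(out_dir)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.device}_{rec.participant_id}_{rec.task_id}_r{rec.repetition}.csv"
        write_recording_csv(rec, rec_dir / fname)
        rows.append(
            {
                "device": rec.device,
                "participant": rec.participant_id,
                "task": rec.task_id,
                "repetition": rec.repetition,
                "nominal_rate": rec.nominal_rate,
                "path": f"recordings/{fname}",
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    write_annotations(annotations, out / "annotations.csv")
    return manifest


def read_dataset(
    data_dir: str | Path,
) -> tuple[list[SensorRecording], list[SymptomAnnotation]]:
    base = Path(data_dir)
    manifest = pd.read_csv(base / "manifest.csv")
    recordings = [
        read_recording_csv(
            base / row.path, row.device, row.participant, row.task,
            int(row.repetition), float(row.nominal_rate),
        )
        for row in manifest.itertuples()
    ]
    annotations = read_annotations(base / "annotations.csv")
    return recordings, annotations


def write_annotations(
    annotations: Sequence[SymptomAnnotation], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "participant": a.participant_id,
                "task": a.task_id,
                "repetition": a.repetition,
                "symptom": a.symptom,
                "score": a.score,
            }
            for a in annotations
        ]
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[SymptomAnnotation]:
    df = pd.read_csv(path)
    for col in ("participant", "task", "repetition", "symptom", "score"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(), start=2):  # line 1 is the header
        if row.symptom not in ("tremor", "bradykinesia"):
            raise ParseError(f"{path}: column 'symptom' invalid at line {i}: {row.symptom!r}")
        if not (float(row.score).is_integer() and 0 <= int(row.score) <= 4):
            raise ParseError(f"{path}: column 'score' out of range 0-4 at line {i}: {row.score}")
        out.append(
            SymptomAnnotation(
                symptom=row.symptom,
                score=int(row.score),
                participant_id=str(row.participant),
                task_id=str(row.task),
                repetition=int(row.repetition),
            )
        )
    return out


def write_clip_store(clips, out_dir: str | Path) -> Path:
    """Persist segmented clips: a metadata CSV plus an NPZ tensor container.

    The CSV (``clips.csv``) holds one row per clip — provenance ids,
    start time, validity flag, raw-coverage count, and score columns — and
    the tensors live in ``clips.npz`` under keys derived from the clip id.
    Returns the metadata path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, tensors = [], {}
    for k, clip in enumerate(clips):
        key = f"clip{k:06d}"
        rows.append(
            {
                "key": key,
                "clip_id": clip.clip_id,
                "device": clip.device,
                "participant": clip.participant_id,
                "task": clip.task_id,
                "repetition": clip.repetition,
                "start_time": clip.start_time,
                "rate": clip.rate,
                "raw_sample_count": clip.raw_sample_count,
                "valid": clip.valid,
                "tremor_score": clip.scores.get("tremor", ""),
                "brady_score": clip.scores.get("bradykinesia", ""),
            }
        )
        tensors[f"{key}_accel"] = clip.accel
        if clip.gyro is not None:
            tensors[f"{key}_gyro"] = clip.gyro
    pd.DataFrame(rows).to_csv(out / "clips.csv", index=False)
    np.savez_compressed(out / "clips.npz", **tensors)
    return out / "clips.csv"


def read_clip_store(store_dir: str | Path):
    """Load clips written by :func:`write_clip_store`."""
    from .preprocess import Clip

    base = Path(store_dir)
    meta = pd.read_csv(base / "clips.csv")
    tensors = np.load(base / "clips.npz")
    clips = []
    for row in meta.itertuples():
        scores = {}
        if not pd.isna(row.tremor_score):
            scores["tremor"] = int(row.tremor_score)
        if not pd.isna(row.brady_score):
            scores["bradykinesia"] = int(row.brady_score)
        gyro_key = f"{row.key}_gyro"
        clips.append(
            Clip(
                device=row.device,
                participant_id=row.participant,
                task_id=row.task,
                repetition=int(row.repetition),
                start_time=float(row.start_time),
                accel=tensors[f"{row.key}_accel"],
                gyro=tensors[gyro_key] if gyro_key in tensors.files else None,
                rate=float(row.rate),
                raw_sample_count=int(row.raw_sample_count),
                valid=bool(row.valid),
                scores=scores,
            )
        )
    return clips


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_results_json(payload: dict, path: str | Path) -> None:
    body = {"schema_version": RESULTS_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=False))
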