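"""Readers and writers for the stream formats.

Skeleton streams come in two text formats:

* ``keypoint_json`` — either a list of frame objects
  ``{"timestamp": t, "lighting": tag, "skeletons": [{"person": id,
  "keypoints": [51 floats], "bbox": [4 floats]}]}`` (the format this package
  writes), or a flat COCO-keypoint-style list of per-person entries with a
  ``timestamp``/``image_id`` field, which is grouped into frames on read.
* ``csv`` — one row per skeleton with columns ``timestamp, person, lighting``
  followed by ``<name>_x, <name>_y, <name>_conf`` for each of the 17
  landmarks; a row with an empty ``person`` cell records an empty frame.

Frames are returned sorted by timestamp; malformed rows raise
:class:`~gericare.core.StreamFormatError` with the line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .core import (
    KEYPOINT_NAMES,
    N_KEYPOINTS,
    FrameRecord,
    PatientState,
    Skeleton,
    StreamFormatError,
    VitalsSeries,
)

__all__ = [
    "read_skeleton_stream",
    "write_skeleton_stream",
    "read_vitals_csv",
    "write_vitals_csv",
    "read_patient_state",
    "write_patient_state",
]

PathLike = Union[str, Path]

_CSV_COLUMNS = ["timestamp", "person", "lighting"] + [
    f"{name}_{suffix}" for name in KEYPOINT_NAMES for suffix in ("x", "y", "conf")
]


def read_skeleton_stream(path: PathLike, format: str = "keypoint_json") -> list[FrameRecord]:
    """Read a skeleton stream; see the module docstring for the formats."""
    if format == "keypoint_json":
        return _read_json(Path(path))
    if format == "csv":
        return _read_csv(Path(path))
    raise ValueError(f"unknown skeleton stream format {format!r}")


def write_skeleton_stream(
    frames: Iterable[FrameRecord], path: PathLike, format: str = "keypoint_json"
) -> None:
    frames = sorted(frames, key=lambda f: f.timestamp)
    if format == "keypoint_json":
        payload = [
            {
                "timestamp": f.timestamp,
                "lighting": f.lighting_tag,
                "skeletons": [
                    {
                        "person": s.person_tag,
                        "keypoints": [v for kp in s.keypoints for v in (kp.x, kp.y, kp.confidence)],
                        "bbox": list(s.bbox),
                    }
                    for s in f.skeletons
                ],
            }
            for f in frames
        ]
        Path(path).write_text(json.dumps(payload, indent=1))
    elif format == "csv":
        rows = []
        for f in frames:
            if not f.skeletons:
                rows.append([f.timestamp, "", f.lighting_tag or ""] + [""] * (3 * N_KEYPOINTS))
            for s in f.skeletons:
                rows.append(
                    [f.timestamp, s.person_tag, f.lighting_tag or ""]
                    + [v for kp in s.keypoints for v in (kp.x, kp.y, kp.confidence)]
                )
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown skeleton stream format {format!r}")


def _read_json(path: Path) -> list[FrameRecord]:
    text = path.read_text()
    if not text.strip():
        return []
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StreamFormatError(f"invalid JSON: {exc}", line=exc.lineno) from exc
    if not isinstance(payload, list):
        raise StreamFormatError("top-level JSON value must be a list")
    if not payload:
        return []
    if isinstance(payload[0], dict) and "skeletons" in payload[0]:
        frames = [_frame_from_obj(i, obj) for i, obj in enumerate(payload)]
    else:
        frames = _frames_from_flat(payload)
    frames.sort(key=lambda f: f.timestamp)
    _check_monotone(frames)
    return frames


def _frame_from_obj(index: int, obj: dict) -> FrameRecord:
    try:
        t = float(obj["timestamp"])
    except (KeyError, TypeError, ValueError):
        raise StreamFormatError(f"frame {index}: missing/invalid timestamp") from None
    skeletons = tuple(
        _skeleton_from_entry(index, t, s.get("person", "unknown"), s)
        for s in obj.get("skeletons", [])
    )
    return FrameRecord(timestamp=t, skeletons=skeletons, lighting_tag=obj.get("lighting"))


def _frames_from_flat(payload: list) -> list[FrameRecord]:
    by_time: dict[float, list[Skeleton]] = {}
    for i, entry in enumerate(payload):
        if not isinstance(entry, dict):
            raise StreamFormatError(f"entry {i}: expected an object")
        t_raw = entry.get("timestamp", entry.get("image_id"))
        if t_raw is None:
            raise StreamFormatError(f"entry {i}: no timestamp or image_id")
        t = float(t_raw)
        person = str(entry.get("person", entry.get("person_id", "unknown")))
        by_time.setdefault(t, []).append(_skeleton_from_entry(i, t, person, entry))
    return [FrameRecord(timestamp=t, skeletons=tuple(sk)) for t, sk in sorted(by_time.items())]


def _skeleton_from_entry(index: int, t: float, person: str, entry: dict) -> Skeleton:
    flat = entry.get("keypoints")
    if flat is None or len(flat) != 3 * N_KEYPOINTS:
        got = 0 if flat is None else len(flat)
        raise StreamFormatError(
            f"entry {index}: 'keypoints' must hold {3 * N_KEYPOINTS} floats, got {got}"
        )
    arr = [[flat[3 * k], flat[3 * k + 1], flat[3 * k + 2]] for k in range(N_KEYPOINTS)]
    bbox = entry.get("bbox")
    bbox = tuple(float(v) for v in bbox) if bbox is not None else None
    import numpy as np

    return Skeleton.from_array(np.array(arr, dtype=float), timestamp=t, person_tag=str(person), bbox=bbox)


def _read_csv(path: Path) -> list[FrameRecord]:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise StreamFormatError(f"missing keypoint columns: {missing}", line=1)
    by_time: dict[float, FrameRecord] = {}
    import numpy as np

    for i, row in df.iterrows():
        lineno = int(i) + 2  # header is line 1
        try:
            t = float(row["timestamp"])
        except ValueError:
            raise StreamFormatError(f"invalid timestamp {row['timestamp']!r}", line=lineno) from None
        lighting = row["lighting"] or None
        prev = by_time.get(t)
        if row["person"] == "":
            skeletons: tuple[Skeleton, ...] = prev.skeletons if prev else ()
        else:
            try:
                arr = np.array(
                    [
                        [
                            float(row[f"{name}_x"]),
                            float(row[f"{name}_y"]),
                            float(row[f"{name}_conf"]),
                        ]
                        for name in KEYPOINT_NAMES
                    ]
                )
            except ValueError:
                raise StreamFormatError("non-numeric keypoint value", line=lineno) from None
            sk = Skeleton.from_array(arr, timestamp=t, person_tag=row["person"])
            skeletons = (prev.skeletons if prev else ()) + (sk,)
        by_time[t] = FrameRecord(timestamp=t, skeletons=skeletons, lighting_tag=lighting)
    frames = [by_time[t] for t in sorted(by_time)]
    _check_monotone(frames)
    return frames


def _check_monotone(frames: Sequence[FrameRecord]) -> None:
    for a, b in zip(frames, frames[1:]):
        if b.timestamp < a.timestamp:
            raise StreamFormatError(
                f"timestamps not non-decreasing: {a.timestamp} then {b.timestamp}"
            )


# ---------------------------------------------------------------------------
# Vitals CSV
# ---------------------------------------------------------------------------

def read_vitals_csv(path: PathLike) -> VitalsSeries:
    """Read a vitals CSV (header ``timestamp,heart_rate,spo2,systolic,
    diastolic,weight,sleep_state,sleep_hours,source``; empty cell = missing)."""
    df = pd.read_csv(path)
    return VitalsSeries(df)


def write_vitals_csv(series: VitalsSeries, path: PathLike) -> None:
    series.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Patient state JSON/CSV
# ---------------------------------------------------------------------------

def read_patient_state(path: PathLike) -> PatientState:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return PatientState.from_dict(json.loads(path.read_text()))
    df = pd.read_csv(path)
    if len(df) != 1:
        raise StreamFormatError("patient-state CSV must contain exactly one row")
    row = {k: v for k, v in df.iloc[0].items() if not pd.isna(v)}
    return PatientState.from_dict(row)


def write_patient_state(state: PatientState, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(state.to_dict(), indent=1))
    else:
        pd.DataFrame([state.to_dict()]).to_csv(path, index=False)
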