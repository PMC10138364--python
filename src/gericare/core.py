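"""Core domain types shared by every stage of the monitoring pipeline.

The vision side of the system consumes per-person, per-frame skeletons of 17
COCO-style anatomical keypoints (nose, eyes, ears, shoulders, elbows, wrists,
hips, knees, ankles) as produced by a pose estimator; the estimator itself is
outside this package, keypoints arrive through the stream readers in
:mod:`gericare.io`.  The wearable side consumes timestamped vitals (heart
rate, SpO2, blood pressure, weight, sleep state/hours) with
last-observation-carried-forward (LOCF) semantics for missing samples.  The
decision-support side consumes a 21-variable patient state record.

Coordinate convention: image pixels, origin at the top-left corner, x grows
rightward, y grows downward, 0-based.  Timestamps are POSIX seconds.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from collections import OrderedDict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KEYPOINT_NAMES",
    "N_KEYPOINTS",
    "DETECTION_THRESHOLD",
    "Keypoint",
    "Skeleton",
    "FrameRecord",
    "PoseLabel",
    "StaticPose",
    "PlanAction",
    "ACTION_SEVERITY",
    "VitalsRecord",
    "VitalsSeries",
    "VITALS_FIELDS",
    "PATIENT_SCHEMA",
    "PatientState",
    "GericareError",
    "SchemaError",
    "StreamFormatError",
]


class GericareError(Exception):
    """Base class for package-specific errors."""


class SchemaError(GericareError, ValueError):
    """A record violates the domain schema (unknown field, bad value)."""


class StreamFormatError(GericareError, ValueError):
    """A stream file is malformed; carries the offending line when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# Canonical keypoint order (COCO-17, the order pose estimators emit).
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)
N_KEYPOINTS = len(KEYPOINT_NAMES)

#: Keypoints with confidence below this are treated as undetected and their
#: coordinates are ignored by all geometry.  Configurable per call site.
DETECTION_THRESHOLD = 0.05


@dataclasses.dataclass(frozen=True)
class Keypoint:
    """One landmark of one person in one frame."""

    name: str
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if self.name not in KEYPOINT_NAMES:
            raise SchemaError(f"unknown keypoint name {self.name!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise SchemaError(
                f"keypoint {self.name}: confidence {self.confidence} not in [0, 1]"
            )

    def detected(self, threshold: float = DETECTION_THRESHOLD) -> bool:
        return self.confidence >= threshold


@dataclasses.dataclass(frozen=True)
class Skeleton:
    """One person's 17 keypoints in one frame; the unit of vision input."""

    timestamp: float
    keypoints: tuple[Keypoint, ...]
    person_tag: str = "unknown"
    bbox: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if len(self.keypoints) != N_KEYPOINTS:
            raise SchemaError(
                f"skeleton must have exactly {N_KEYPOINTS} keypoints, "
                f"got {len(self.keypoints)}"
            )
        names = tuple(kp.name for kp in self.keypoints)
        if names != KEYPOINT_NAMES:
            raise SchemaError("keypoints are not in canonical COCO-17 order")
        if self.bbox is None:
            object.__setattr__(self, "bbox", self._bbox_from_keypoints())

    def _bbox_from_keypoints(self) -> tuple[float, float, float, float]:
        pts = self.detected_xy()
        if len(pts) == 0:
            return (0.0, 0.0, 0.0, 0.0)
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )

    def keypoint(self, name: str) -> Keypoint:
        return self.keypoints[KEYPOINT_NAMES.index(name)]

    def as_array(self) -> np.ndarray:
        """(17, 3) array of x, y, confidence in canonical order."""
        return np.array(
            [[kp.x, kp.y, kp.confidence] for kp in self.keypoints], dtype=float
        )

    def detected_mask(self, threshold: float = DETECTION_THRESHOLD) -> np.ndarray:
        return np.array([kp.detected(threshold) for kp in self.keypoints])

    def detected_xy(self, threshold: float = DETECTION_THRESHOLD) -> np.ndarray:
        arr = self.as_array()
        return arr[self.detected_mask(threshold), :2]

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        timestamp: float,
        person_tag: str = "unknown",
        bbox: Optional[tuple[float, float, float, float]] = None,
    ) -> "Skeleton":
        """Build from a (17, 3) array of x, y, confidence rows."""
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_KEYPOINTS, 3):
            raise SchemaError(f"expected shape (17, 3), got {arr.shape}")
        kps = tuple(
            Keypoint(name, float(x), float(y), float(c))
            for name, (x, y, c) in zip(KEYPOINT_NAMES, arr)
        )
        return cls(timestamp=timestamp, keypoints=kps, person_tag=person_tag, bbox=bbox)


@dataclasses.dataclass(frozen=True)
class FrameRecord:
    """All skeletons detected at one timestamp, plus scene metadata.

    ``lighting_tag`` (well_lit / semi_lit / poorly_lit) is logging metadata
    only; it never alters any geometry.
    """

    timestamp: float
    skeletons: tuple[Skeleton, ...] = ()
    lighting_tag: Optional[str] = None


class PoseLabel(str, enum.Enum):
    """Final per-minute activity classes.

    ``UNDETERMINED`` is internal to the verification protocol; per-minute
    outputs carry one of the six public classes.
    """

    WALKING = "walking"
    STANDING = "standing"
    SITTING = "sitting"
    FALLEN_ON_GROUND = "fallen_on_ground"
    LYING_IN_BED = "lying_in_bed"
    SLEEPING = "sleeping"
    UNDETERMINED = "undetermined"


#: The six classes a minute can be labelled with.
FINAL_POSE_LABELS: tuple[PoseLabel, ...] = (
    PoseLabel.WALKING,
    PoseLabel.STANDING,
    PoseLabel.SITTING,
    PoseLabel.FALLEN_ON_GROUND,
    PoseLabel.LYING_IN_BED,
    PoseLabel.SLEEPING,
)


class StaticPose(str, enum.Enum):
    """Single-frame geometric classes.

    ``UPRIGHT`` is later split into walking/standing and ``LYING_LIKE`` into
    lying_in_bed/sleeping; both splits are temporal, never static.
    """

    UPRIGHT = "upright"
    SITTING = "sitting"
    FALLEN_ON_GROUND = "fallen_on_ground"
    LYING_LIKE = "lying_like"
    UNKNOWN = "unknown"


class PlanAction(str, enum.Enum):
    """The four care-plan outputs; the default is CONTINUE."""

    CONTINUE = "continue_current_treatment"
    MONITOR = "monitor"
    ADJUST = "adjust"
    EXTRA = "extra_situation"


#: Higher number = more urgent.  Used for rule ordering and tie-breaking so
#: an emergency is never masked by a blander recommendation.
ACTION_SEVERITY: dict[PlanAction, int] = {
    PlanAction.CONTINUE: 0,
    PlanAction.MONITOR: 1,
    PlanAction.ADJUST: 2,
    PlanAction.EXTRA: 3,
}


# ---------------------------------------------------------------------------
# Vitals
# ---------------------------------------------------------------------------

VITALS_FIELDS: tuple[str, ...] = (
    "heart_rate",
    "spo2",
    "systolic",
    "diastolic",
    "weight",
    "sleep_state",
    "sleep_hours",
)

_POSITIVE_FIELDS = ("heart_rate", "spo2", "systolic", "diastolic", "weight")


@dataclasses.dataclass(frozen=True)
class VitalsRecord:
    """One timestamped wearable/device measurement; None means missing."""

    timestamp: float
    heart_rate: Optional[float] = None
    spo2: Optional[float] = None
    systolic: Optional[float] = None
    diastolic: Optional[float] = None
    weight: Optional[float] = None
    sleep_state: Optional[bool] = None
    sleep_hours: Optional[float] = None
    source: str = "wearable"

    def __post_init__(self) -> None:
        for f in _POSITIVE_FIELDS:
            v = getattr(self, f)
            if v is not None and not v > 0:
                raise SchemaError(f"{f}={v} must be positive when present")
        if self.sleep_hours is not None and not (0.0 <= self.sleep_hours <= 24.0):
            raise SchemaError(f"sleep_hours={self.sleep_hours} not in [0, 24]")


class VitalsSeries:
    """A timestamp-sorted series of vitals, backed by a pandas DataFrame.

    Missing values are NaN (numeric fields) or None (sleep_state).  The
    series is sorted by timestamp on construction.
    """

    #: Default staleness bound for carry-forward imputation: 24 hours.  The
    #: carry-forward rule itself has no bound; one is imposed so a vanished
    #: wearable cannot feed day-old vitals into decisions silently.
    DEFAULT_MAX_STALENESS = 24 * 3600.0

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "timestamp" not in frame.columns:
            raise SchemaError("vitals frame needs a 'timestamp' column")
        for f in VITALS_FIELDS:
            if f not in frame.columns:
                frame[f] = np.nan
        if "source" not in frame.columns:
            frame["source"] = "wearable"
        frame = frame[["timestamp", *VITALS_FIELDS, "source"]]
        frame = frame.sort_values("timestamp", kind="stable").reset_index(drop=True)
        for f in _POSITIVE_FIELDS:
            col = pd.to_numeric(frame[f], errors="coerce")
            bad = col.notna() & ~(col > 0)
            if bad.any():
                raise SchemaError(f"non-positive value in vitals field {f!r}")
            frame[f] = col
        sh = pd.to_numeric(frame["sleep_hours"], errors="coerce")
        if ((sh < 0) | (sh > 24)).any():
            raise SchemaError("sleep_hours outside [0, 24]")
        frame["sleep_hours"] = sh
        frame["sleep_state"] = frame["sleep_state"].map(_coerce_bool)
        self._frame = frame
        # which cells hold true measurements (carried-forward copies are not);
        # staleness is always counted from a real measurement
        self._observed: dict[str, np.ndarray] = {
            f: np.array([not _is_missing(v) for v in frame[f]]) for f in VITALS_FIELDS
        }

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VitalsSeries):
            return NotImplemented
        return self._frame.equals(other._frame)

    @classmethod
    def from_records(cls, records: Iterable[VitalsRecord]) -> "VitalsSeries":
        rows = [dataclasses.asdict(r) for r in records]
        return cls(pd.DataFrame(rows, columns=["timestamp", *VITALS_FIELDS, "source"]))

    def locf_fill(
        self,
        field: Optional[str] = None,
        max_staleness: float = DEFAULT_MAX_STALENESS,
    ) -> "VitalsSeries":
        """Carry the last observed value forward across gaps.

        A missing sample is replaced by the most recent *measured* value no
        older than ``max_staleness`` seconds; older gaps remain missing and
        observed values are never changed.  Carried-forward copies do not
        count as measurements, so applying the fill twice equals applying it
        once.  ``field=None`` fills every vitals field.
        """
        if field is None:
            fields: Sequence[str] = VITALS_FIELDS
        else:
            if field not in VITALS_FIELDS:
                raise SchemaError(f"unknown vitals field {field!r}")
            fields = (field,)
        frame = self._frame.copy()
        t = frame["timestamp"].to_numpy(dtype=float)
        n = len(frame)
        for f in fields:
            vals = frame[f].to_numpy(dtype=object)
            obs = self._observed[f].copy()
            if n == 0 or not obs.any():
                continue
            last = np.where(obs, np.arange(n), -1)
            last = np.maximum.accumulate(last)
            for i in range(n):
                j = last[i]
                if not obs[i] and j >= 0 and t[i] - t[j] <= max_staleness:
                    vals[i] = vals[j]
            if f == "sleep_state":
                frame[f] = vals
            else:
                frame[f] = pd.to_numeric(pd.Series(vals), errors="coerce")
        out = VitalsSeries(frame)
        out._observed = {f: self._observed[f].copy() for f in VITALS_FIELDS}
        return out

    def between(self, t0: float, t1: float) -> pd.DataFrame:
        """Rows with t0 <= timestamp < t1."""
        f = self._frame
        return f[(f["timestamp"] >= t0) & (f["timestamp"] < t1)].copy()


def _coerce_bool(v: object) -> Optional[bool]:
    if _is_missing(v):
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, float, np.integer, np.floating)):
        return bool(v)
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise SchemaError(f"cannot interpret sleep_state value {v!r}")
    raise SchemaError(f"cannot interpret sleep_state value {v!r}")


def _is_missing(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if v is pd.NA or v is pd.NaT:
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


# ---------------------------------------------------------------------------
# Patient state
# ---------------------------------------------------------------------------

#: The 21 input variables of the patient record, each with its closed value
#: set.  The clinical source lists several sets as open ("etc."); the open
#: tails are closed here with representative members so that the schema is
#: checkable and the state space finite.
PATIENT_SCHEMA: "OrderedDict[str, tuple[str, ...]]" = OrderedDict(
    [
        (
            "MoveC",
            (
                "independent",
                "with assistive devices",
                "sitting in a wheelchair",
                "lying",
            ),
        ),
        ("RiskC", ("none", "low", "medium", "high")),
        ("Bedsores", ("no", "yes")),
        (
            "Diseases",
            ("none", "heart failure", "alzheimer", "dementia", "cancer", "diabetes"),
        ),
        ("Med", ("none", "antibiotics", "antihypertensives", "antidepressants")),
        (
            "BMI",
            (
                "stable",
                "<0.5 plus",
                "<0.5 minus",
                "0.5-1 plus",
                "0.5-1 minus",
                ">1 plus",
                ">1 minus",
            ),
        ),
        ("MoveH", ("unchanged", "slowed down", "increased", "falling on the ground")),
        (
            "EatH",
            ("independent eating", "fed by another person", "parenteral nutrition"),
        ),
        (
            "EatC",
            (
                "swallows solid food",
                "swallows only mashed food",
                "swallows only liquids",
            ),
        ),
        (
            "Bowel",
            (
                "regular bowel movements",
                "diarrhoea",
                "constipation",
                "faecal incontinence",
            ),
        ),
        ("Sleep", ("<4 h", "4-6 h", "6-8 h", ">8 h", "apnoea")),
        ("Breath", ("normal", "increased", "slowing down", "with apnoeas")),
        ("PL", ("normal", "bradycardia", "tachycardia")),
        (
            "BP",
            (
                "normotension",
                "hypotension",
                "hypertension mild",
                "hypertension moderate",
                "hypertension severe",
            ),
        ),
        ("Temp", ("36.0-37.4 C", "<36.0 C", "37.5-38.0 C", ">38.0 C")),
        ("Sat", (">=94%", "<94%")),
        (
            "Urine",
            ("normal", "concentrated urine", "very frequent", "anuria"),
        ),
        ("Fluid", (">=500 mL", "<500 mL")),
        ("Gly", (">=2.5 mmol/l", "<2.5 mmol/l")),
        ("Con", ("unchanged", "changed", "unconscious")),
        ("Pain", ("none", "mild", "moderate", "severe", "unbearable")),
    ]
)

HEIGHT_RANGE = (1.20, 2.20)  # metres


@dataclasses.dataclass(frozen=True)
class PatientState:
    """One patient record: the 21 schema variables plus demographics."""

    values: Mapping[str, str]
    first_name: str = ""
    last_name: str = ""
    birth_date: str = ""
    height: Optional[float] = None

    def __post_init__(self) -> None:
        values = dict(self.values)
        unknown = sorted(set(values) - set(PATIENT_SCHEMA))
        if unknown:
            raise SchemaError(f"unknown patient variables: {unknown}")
        missing = sorted(set(PATIENT_SCHEMA) - set(values))
        if missing:
            raise SchemaError(f"missing patient variables: {missing}")
        bad = [
            f"{var}={values[var]!r}"
            for var in PATIENT_SCHEMA
            if values[var] not in PATIENT_SCHEMA[var]
        ]
        if bad:
            raise SchemaError("values outside schema: " + ", ".join(bad))
        if self.height is not None and not (
            HEIGHT_RANGE[0] <= self.height <= HEIGHT_RANGE[1]
        ):
            raise SchemaError(
                f"height {self.height} m outside [{HEIGHT_RANGE[0]}, {HEIGHT_RANGE[1]}]"
            )
        object.__setattr__(self, "values", values)

    def __getitem__(self, var: str) -> str:
        return self.values[var]

    def to_dict(self) -> dict:
        d = dict(self.values)
        d.update(
            first_name=self.first_name,
            last_name=self.last_name,
            birth_date=self.birth_date,
            height=self.height,
        )
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PatientState":
        d = dict(d)
        demo = {
            k: d.pop(k)
            for k in ("first_name", "last_name", "birth_date", "height")
            if k in d
        }
        return cls(values={k: str(v) for k, v in d.items()}, **demo)  # type: ignore[arg-type]
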