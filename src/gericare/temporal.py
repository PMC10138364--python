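"""The timed assessment protocol over skeleton streams.

The camera runs at 10 FPS but a pose is assessed only every 5 seconds, on
the assumption that no significant motion change happens faster.  Three
consecutive assessments spanning 15 s verify a pose by 2-of-3 majority:
an upright majority becomes *walking* when the mean inter-assessment motion
score exceeds a threshold and *standing* otherwise; a lying-like majority is
held for up to a minute and disambiguated into *lying in bed* vs *sleeping*
by fusing the window's motion with the wristband (sleep flag and heart rate
relative to a personal awake baseline); two or more fallen assessments yield
*fallen on the ground* immediately regardless of the third (severity bias).
The pose is then reassessed every minute, and per-minute labels accumulate
into a daily activity ledger (hours per pose per calendar day) that feeds
the movement-habit change detector.

The motion score between two skeletons is the mean Euclidean displacement
of commonly detected keypoints normalized by the mean torso length, so 1.0
means "moved by one torso length".
"""

from __future__ import annotations

import dataclasses
import enum
from collections import defaultdict
from datetime import datetime, timezone, timedelta
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    DETECTION_THRESHOLD,
    FrameRecord,
    PoseLabel,
    Skeleton,
    VitalsSeries,
)
from .posture import PoseModel, StaticPose, classify_static, extract_features

__all__ = [
    "VerifiedPose",
    "AssessmentWindow",
    "ActivityLedger",
    "MonitorConfig",
    "sample_assessments",
    "motion_score",
    "verify_pose",
    "disambiguate_lying",
    "monitor",
]


class VerifiedPose(str, enum.Enum):
    """Outcome of the 3-frame verification; LYING_LIKE is deferred to the
    one-minute wearable fusion and never emitted as a final label."""

    WALKING = "walking"
    STANDING = "standing"
    SITTING = "sitting"
    FALLEN_ON_GROUND = "fallen_on_ground"
    LYING_LIKE = "lying_like"
    UNDETERMINED = "undetermined"


@dataclasses.dataclass(frozen=True)
class AssessmentWindow:
    """Exactly three (timestamp, static pose, skeleton) assessment triples
    spaced by the sampling period."""

    assessments: tuple[tuple[float, StaticPose, Skeleton], ...]
    subject_tag: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.assessments) != 3:
            raise ValueError("an assessment window holds exactly 3 assessments")


@dataclasses.dataclass
class MonitorConfig:
    """Protocol parameters; values are package defaults, all configurable."""

    period: float = 5.0  # seconds between assessments
    motion_threshold: float = 0.05  # walking vs standing, torso lengths
    still_threshold: float = 0.02  # sleeping stillness, torso lengths
    hr_margin: float = 10.0  # bpm below awake baseline that suggests sleep
    baseline_hr: float = 70.0  # fallback when no awake history exists
    max_inherit_minutes: int = 5  # undetermined minutes inherit the previous pose
    timezone_offset_hours: float = 0.0  # calendar days for the ledger
    detection_threshold: float = DETECTION_THRESHOLD


def sample_assessments(
    stream: Iterable[FrameRecord], period: float = 5.0
) -> dict[str, list[tuple[float, Skeleton]]]:
    """One assessment per ``period`` seconds per tracked subject.

    For every subject the first frame at or after each period boundary
    (t0, t0+period, ...) supplies the assessment skeleton; at 10 FPS and a
    60 s stream this inspects 600 frames and keeps 12 assessments per
    subject.  Returns {subject_tag: [(timestamp, skeleton), ...]}.
    """
    frames = sorted(stream, key=lambda f: f.timestamp)
    out: dict[str, list[tuple[float, Skeleton]]] = defaultdict(list)
    if not frames:
        return dict(out)
    t0 = frames[0].timestamp
    next_due: dict[str, float] = {}
    for frame in frames:
        for sk in frame.skeletons:
            due = next_due.get(sk.person_tag, t0)
            if frame.timestamp >= due:
                out[sk.person_tag].append((frame.timestamp, sk))
                # schedule the next boundary strictly after this frame
                k = int(np.floor((frame.timestamp - t0) / period)) + 1
                next_due[sk.person_tag] = t0 + k * period
    return dict(out)


def motion_score(
    a: Skeleton, b: Skeleton, threshold: float = DETECTION_THRESHOLD
) -> Optional[float]:
    """Normalized displacement between two skeletons of the same subject.

    Mean Euclidean displacement over commonly detected keypoints divided by
    the mean torso length of the two skeletons; symmetric in (a, b).
    Returns None (undefined) when fewer than 3 keypoints are commonly
    detected or no torso length is measurable.
    """
    mask = a.detected_mask(threshold) & b.detected_mask(threshold)
    if mask.sum() < 3:
        return None
    pa = a.as_array()[mask, :2]
    pb = b.as_array()[mask, :2]
    disp = float(np.linalg.norm(pa - pb, axis=1).mean())
    torso = []
    for sk in (a, b):
        f = extract_features(sk, threshold)
        if f.reliable and f.torso_length > 1e-9:
            torso.append(f.torso_length)
    if not torso:
        return None
    return disp / float(np.mean(torso))


def verify_pose(
    window: AssessmentWindow,
    model: Optional[PoseModel] = None,
    motion_threshold: float = 0.05,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> VerifiedPose:
    """2-of-3 majority verification of a window.

    Severity bias: two or more fallen assessments verify fallen_on_ground
    immediately.  An upright majority splits into walking/standing on the
    mean motion score; a lying-like majority defers to
    :func:`disambiguate_lying`.  No majority yields undetermined.  Sleeping
    is never produced here.
    """
    statics = []
    for t, pose, sk in window.assessments:
        if pose is None:
            pose, _ = classify_static(extract_features(sk, detection_threshold), model)
        statics.append(StaticPose(pose))
    n_fallen = sum(p is StaticPose.FALLEN_ON_GROUND for p in statics)
    if n_fallen >= 2:
        return VerifiedPose.FALLEN_ON_GROUND
    counts: dict[StaticPose, int] = {}
    for p in statics:
        counts[p] = counts.get(p, 0) + 1
    majority = max(counts, key=lambda p: counts[p])
    if counts[majority] < 2 or majority is StaticPose.UNKNOWN:
        return VerifiedPose.UNDETERMINED
    if majority is StaticPose.SITTING:
        return VerifiedPose.SITTING
    if majority is StaticPose.LYING_LIKE:
        return VerifiedPose.LYING_LIKE
    if majority is StaticPose.FALLEN_ON_GROUND:
        return VerifiedPose.FALLEN_ON_GROUND
    # upright: split on motion
    scores = []
    skels = [sk for _, _, sk in window.assessments]
    for u, v in zip(skels, skels[1:]):
        s = motion_score(u, v, detection_threshold)
        if s is not None:
            scores.append(s)
    if scores and float(np.mean(scores)) > motion_threshold:
        return VerifiedPose.WALKING
    return VerifiedPose.STANDING


def disambiguate_lying(
    assessments: Sequence[tuple[float, Skeleton]],
    vitals: Optional[VitalsSeries],
    baseline_hr: float,
    still_threshold: float = 0.02,
    hr_margin: float = 10.0,
    detection_threshold: float = DETECTION_THRESHOLD,
) -> tuple[PoseLabel, bool]:
    """Split a minute of lying-like assessments into lying_in_bed/sleeping.

    The subject is sleeping iff the wristband reports sleep_state true
    anywhere in the window, OR the mean motion over the minute is below the
    stillness threshold AND the mean heart rate is at least ``hr_margin``
    bpm below the personal awake baseline.  Entirely missing vitals fall
    back to motion alone and flag the decision low-confidence.

    Returns (label, low_confidence).
    """
    if len(assessments) < 2:
        return PoseLabel.LYING_IN_BED, True
    t0 = assessments[0][0]
    t1 = assessments[-1][0]
    scores = []
    for (ta, a), (tb, b) in zip(assessments, assessments[1:]):
        s = motion_score(a, b, detection_threshold)
        if s is not None:
            scores.append(s)
    still = bool(scores) and float(np.mean(scores)) < still_threshold

    sleep_flag = False
    mean_hr: Optional[float] = None
    if vitals is not None:
        rows = vitals.between(t0, t1 + 1e-9)
        if len(rows):
            states = [s for s in rows["sleep_state"] if s is not None]
            sleep_flag = any(bool(s) for s in states)
            hr = rows["heart_rate"].dropna()
            if len(hr):
                mean_hr = float(hr.mean())
    if sleep_flag:
        return PoseLabel.SLEEPING, False
    if mean_hr is None:
        # no usable vitals: motion alone, low confidence
        return (PoseLabel.SLEEPING if still else PoseLabel.LYING_IN_BED), True
    if still and mean_hr <= baseline_hr - hr_margin:
        return PoseLabel.SLEEPING, False
    return PoseLabel.LYING_IN_BED, False


class ActivityLedger:
    """Hours spent in each of the six pose classes per calendar day."""

    def __init__(self, subject_tag: str = "unknown", timezone_offset_hours: float = 0.0):
        self.subject_tag = subject_tag
        self.tz = timezone(timedelta(hours=timezone_offset_hours))
        self._hours: dict[str, dict[str, float]] = defaultdict(
            lambda: {p.value: 0.0 for p in PoseLabel if p is not PoseLabel.UNDETERMINED}
        )

    def day_of(self, timestamp: float) -> str:
        return datetime.fromtimestamp(timestamp, tz=self.tz).date().isoformat()

    def add_minutes(self, timestamp: float, pose: PoseLabel, minutes: float = 1.0) -> None:
        if pose is PoseLabel.UNDETERMINED:
            raise ValueError("the ledger records only final pose labels")
        day = self.day_of(timestamp)
        self._hours[day][PoseLabel(pose).value] += minutes / 60.0
        if self.total_hours(day) > 24.0 + 1e-9:
            raise ValueError(f"ledger for {day} exceeds 24 h")

    def hours(self, day: str, pose: Union[PoseLabel, str]) -> float:
        return self._hours.get(day, {}).get(PoseLabel(pose).value, 0.0)

    def total_hours(self, day: str) -> float:
        return sum(self._hours.get(day, {}).values())

    @property
    def days(self) -> list[str]:
        return sorted(self._hours)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"day": d, **self._hours[d]} for d in self.days]
        cols = ["day"] + [p.value for p in PoseLabel if p is not PoseLabel.UNDETERMINED]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject_tag: str = "unknown") -> "ActivityLedger":
        ledger = cls(subject_tag=subject_tag)
        for _, row in frame.iterrows():
            for p in PoseLabel:
                if p is PoseLabel.UNDETERMINED:
                    continue
                if p.value in row and not pd.isna(row[p.value]):
                    ledger._hours[str(row["day"])][p.value] += float(row[p.value])
        return ledger

    @classmethod
    def read_csv(cls, path, subject_tag: str = "unknown") -> "ActivityLedger":
        return cls.from_frame(pd.read_csv(path), subject_tag=subject_tag)


@dataclasses.dataclass
class MinuteLabel:
    minute: float  # start timestamp of the minute
    subject: str
    pose: PoseLabel
    low_confidence: bool = False
    alert: bool = False


def monitor(
    stream: Iterable[FrameRecord],
    vitals: Optional[Union[VitalsSeries, Mapping[str, VitalsSeries]]] = None,
    model: Optional[PoseModel] = None,
    config: Optional[MonitorConfig] = None,
) -> tuple[list[MinuteLabel], dict[str, ActivityLedger], list[MinuteLabel]]:
    """Run the full per-minute protocol over a stream.

    Returns (minute labels, {subject: ledger}, alert events).  A subject
    absent for a whole minute produces no label for it (a gap, not an
    error); an undetermined verification inherits the previous verified
    pose for at most ``config.max_inherit_minutes`` consecutive minutes.
    Every fallen_on_ground minute emits an alert event.
    """
    cfg = config or MonitorConfig()
    frames = sorted(stream, key=lambda f: f.timestamp)
    labels: list[MinuteLabel] = []
    alerts: list[MinuteLabel] = []
    ledgers: dict[str, ActivityLedger] = {}
    if not frames:
        return labels, ledgers, alerts
    assessments = sample_assessments(frames, period=cfg.period)
    t0 = frames[0].timestamp
    t_end = frames[-1].timestamp

    for subject, assess in assessments.items():
        ledger = ActivityLedger(subject, cfg.timezone_offset_hours)
        ledgers[subject] = ledger
        vit = vitals.get(subject) if isinstance(vitals, Mapping) else vitals
        if vit is not None:
            vit = vit.locf_fill()
        baseline = _awake_baseline(vit, cfg.baseline_hr)
        prev_pose: Optional[PoseLabel] = None
        inherited = 0
        minute = t0
        while minute <= t_end:
            in_minute = [(t, sk) for t, sk in assess if minute <= t < minute + 60.0]
            if not in_minute:
                prev_pose, inherited = None, 0  # subject absent: gap
                minute += 60.0
                continue
            label: Optional[PoseLabel] = None
            low_conf = False
            if len(in_minute) >= 3:
                triples = tuple(
                    (t, None, sk) for t, sk in in_minute[:3]
                )
                window = AssessmentWindow(assessments=triples, subject_tag=subject)
                verdict = verify_pose(
                    window, model, cfg.motion_threshold, cfg.detection_threshold
                )
            else:
                verdict = VerifiedPose.UNDETERMINED
            if verdict is VerifiedPose.LYING_LIKE:
                label, low_conf = disambiguate_lying(
                    in_minute,
                    vit,
                    baseline,
                    cfg.still_threshold,
                    cfg.hr_margin,
                    cfg.detection_threshold,
                )
            elif verdict is not VerifiedPose.UNDETERMINED:
                label = PoseLabel(verdict.value)
            if label is None:
                if prev_pose is not None and inherited < cfg.max_inherit_minutes:
                    label = prev_pose
                    inherited += 1
                    low_conf = True
            else:
                inherited = 0
            if label is not None:
                rec = MinuteLabel(
                    minute=minute,
                    subject=subject,
                    pose=label,
                    low_confidence=low_conf,
                    alert=label is PoseLabel.FALLEN_ON_GROUND,
                )
                labels.append(rec)
                ledger.add_minutes(minute, label)
                if rec.alert:
                    alerts.append(rec)
                prev_pose = label
            else:
                prev_pose, inherited = None, 0
            minute += 60.0
    labels.sort(key=lambda r: (r.minute, r.subject))
    return labels, ledgers, alerts


def _awake_baseline(vitals: Optional[VitalsSeries], fallback: float) -> float:
    """Trailing median of awake-period heart rate; the personal baseline."""
    if vitals is None or len(vitals) == 0:
        return fallback
    f = vitals.frame
    awake = f[[s is not True for s in f["sleep_state"]]]["heart_rate"].dropna()
    if len(awake) == 0:
        awake = f["heart_rate"].dropna()
    if len(awake) == 0:
        return fallback
    return float(awake.median())
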