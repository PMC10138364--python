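"""Synthetic ward data with ground truth.

Real footage and vitals of nursing-home patients are private; every input
the pipeline consumes is therefore emulated here, with ground-truth labels
attached, so each stage can be exercised and measured without any download:

* articulated 2-D stick-figure skeleton streams per scripted pose timeline
  (standing = vertical torso, walking = translation + limb oscillation,
  sitting = ~90 deg hip flexion, lying/fallen = horizontal torso inside /
  outside the bed region, sleeping = lying with no voluntary motion), with
  isotropic Gaussian keypoint noise and per-keypoint dropout emulating
  blanket occlusion;
* wristband vitals with a circadian heart-rate term, scripted sleep
  intervals (heart rate reduced, sleep flag raised), and scripted dropouts
  for carry-forward testing;
* patient-state records sampled from the 21-variable schema and labelled by
  the rule engine (the oracle for tree training);
* small procedural ward images with per-identity textures for the
  bag-of-visual-words re-identification benchmark.

Every generator is a pure function of (script/params, seed).  The default
scene is 640x480 px with the bed occupying the right side; a 1.7 m person
is about 160 px tall.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .careplan import RuleSet, evaluate_rules
from .core import (
    PATIENT_SCHEMA,
    FrameRecord,
    PatientState,
    PlanAction,
    PoseLabel,
    Skeleton,
    VitalsSeries,
)
from .posture import DEFAULT_BED_REGION, StaticPose

__all__ = [
    "Segment",
    "ScenarioScript",
    "script_from_schedule",
    "generate_skeleton_sequence",
    "generate_vitals",
    "generate_patient_states",
    "generate_labelled_skeletons",
    "generate_ward_images",
    "write_ward_images",
    "DEFAULT_PRIORS",
    "SCENE_WIDTH",
    "SCENE_HEIGHT",
]

SCENE_WIDTH = 640
SCENE_HEIGHT = 480
FLOOR_Y = 460.0
DEFAULT_SCALE = 160.0  # pixels per unit body height

# Canonical unit-body template, y up, origin at mid-ankle ground point.
_TEMPLATE: dict[str, tuple[float, float]] = {
    "nose": (0.0, 0.93),
    "left_eye": (-0.02, 0.95),
    "right_eye": (0.02, 0.95),
    "left_ear": (-0.045, 0.94),
    "right_ear": (0.045, 0.94),
    "left_shoulder": (-0.10, 0.82),
    "right_shoulder": (0.10, 0.82),
    "left_elbow": (-0.13, 0.67),
    "right_elbow": (0.13, 0.67),
    "left_wrist": (-0.14, 0.50),
    "right_wrist": (0.14, 0.50),
    "left_hip": (-0.06, 0.53),
    "right_hip": (0.06, 0.53),
    "left_knee": (-0.07, 0.28),
    "right_knee": (0.07, 0.28),
    "left_ankle": (-0.07, 0.0),
    "right_ankle": (0.07, 0.0),
}

_ORDER = tuple(_TEMPLATE)  # canonical COCO-17 order by construction


@dataclasses.dataclass(frozen=True)
class Segment:
    """One scripted stretch of a single true pose."""

    start: float
    end: float
    pose: PoseLabel
    amplitude: float = 1.0  # walking speed factor / awake-lying fidget factor

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"segment end {self.end} must exceed start {self.start}")
        PoseLabel(self.pose)


@dataclasses.dataclass
class ScenarioScript:
    """Per-subject timeline plus vitals profile; seed fully determines output."""

    subject_tag: str
    segments: tuple[Segment, ...]
    seed: int = 0
    baseline_hr: float = 70.0
    hr_sleep_drop: float = 15.0
    sleep_intervals: tuple[tuple[float, float], ...] = ()
    vitals_dropout: float = 0.0
    noise_frac: float = 0.01  # keypoint noise sigma as a fraction of torso length
    occlusion_prob: float = 0.02  # per-keypoint dropout probability
    walking_speed: float = 40.0  # px/s
    bed_region: tuple[tuple[float, float], ...] = DEFAULT_BED_REGION
    scale: float = DEFAULT_SCALE
    lighting: tuple[tuple[float, float, str], ...] = ()

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"segments overlap at t={b.start}")
        if self.baseline_hr <= 0:
            raise ValueError("baseline_hr must be positive")
        self.segments = tuple(segs)

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def true_label(self, t: float) -> Optional[PoseLabel]:
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return PoseLabel(seg.pose)
        return None

    def lighting_at(self, t: float) -> Optional[str]:
        for t0, t1, tag in self.lighting:
            if t0 <= t < t1:
                return tag
        return None


def script_from_schedule(
    subject_tag: str,
    start: float,
    schedule: Sequence[tuple[Union[PoseLabel, str], float]],
    **kwargs,
) -> ScenarioScript:
    """Build a script from (pose, duration seconds) entries back to back."""
    segments = []
    t = start
    for pose, duration in schedule:
        segments.append(Segment(start=t, end=t + duration, pose=PoseLabel(pose)))
        t += duration
    return ScenarioScript(subject_tag=subject_tag, segments=tuple(segments), **kwargs)


# ---------------------------------------------------------------------------
# Stick-figure synthesis
# ---------------------------------------------------------------------------

def _standing_points(swing: float = 0.0) -> dict[str, tuple[float, float]]:
    pts = dict(_TEMPLATE)
    if swing:
        for side, sgn in (("left", 1.0), ("right", -1.0)):
            for name, gain in ((f"{side}_knee", 0.10), (f"{side}_ankle", 0.16), (f"{side}_wrist", -0.12)):
                x, y = pts[name]
                pts[name] = (x + sgn * gain * swing, y)
    return pts


def _sitting_points() -> dict[str, tuple[float, float]]:
    return {
        "nose": (0.0, 0.86),
        "left_eye": (-0.02, 0.88),
        "right_eye": (0.02, 0.88),
        "left_ear": (-0.045, 0.87),
        "right_ear": (0.045, 0.87),
        "left_shoulder": (-0.10, 0.74),
        "right_shoulder": (0.10, 0.74),
        "left_elbow": (-0.12, 0.60),
        "right_elbow": (0.12, 0.60),
        "left_wrist": (-0.13, 0.48),
        "right_wrist": (0.13, 0.48),
        "left_hip": (-0.05, 0.45),
        "right_hip": (0.05, 0.45),
        "left_knee": (0.28, 0.45),
        "right_knee": (0.32, 0.45),
        "left_ankle": (0.28, 0.17),
        "right_ankle": (0.32, 0.17),
    }


def _lying_points() -> dict[str, tuple[float, float]]:
    """Standing template rotated onto its back: body along +x, feet at x=0."""
    return {name: (y, x) for name, (x, y) in _TEMPLATE.items()}


def _rotate(pts: dict[str, tuple[float, float]], deg: float) -> dict[str, tuple[float, float]]:
    if deg == 0:
        return pts
    arr = np.array(list(pts.values()))
    c = arr.mean(axis=0)
    th = math.radians(deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    arr = (arr - c) @ rot.T + c
    return {name: (float(x), float(y)) for name, (x, y) in zip(pts, arr)}


def _to_pixels(
    pts: dict[str, tuple[float, float]],
    anchor: tuple[float, float],
    scale: float,
) -> np.ndarray:
    """Unit y-up coordinates -> image pixels (y down); (17, 2) array."""
    out = np.empty((len(_ORDER), 2))
    for i, name in enumerate(_ORDER):
        x, y = pts[name]
        out[i, 0] = anchor[0] + x * scale
        out[i, 1] = anchor[1] - y * scale
    return out


def _bed_anchor(bed_region, scale) -> tuple[float, float]:
    xs = [p[0] for p in bed_region]
    ys = [p[1] for p in bed_region]
    # feet end near the left edge of the bed, body axis along +x
    return (min(xs) + 15.0, (min(ys) + max(ys)) / 2.0)


def _pose_pixels(
    pose: PoseLabel,
    t: float,
    seg: Segment,
    script: ScenarioScript,
    anchor_cache: dict,
    rng: np.random.Generator,
) -> np.ndarray:
    scale = script.scale
    if pose is PoseLabel.WALKING:
        swing = math.sin(2 * math.pi * 1.5 * t)
        pts = _standing_points(swing=seg.amplitude * swing)
        span = (60.0, SCENE_WIDTH - 60.0)
        dist = script.walking_speed * seg.amplitude * (t - seg.start)
        width = span[1] - span[0]
        x = span[0] + abs((dist % (2 * width)) - width)  # bounce off the walls
        return _to_pixels(pts, (x, FLOOR_Y), scale)
    if pose is PoseLabel.STANDING:
        key = ("standing", seg.start)
        if key not in anchor_cache:
            anchor_cache[key] = (float(rng.uniform(80, 360)), FLOOR_Y)
        return _to_pixels(_standing_points(), anchor_cache[key], scale)
    if pose is PoseLabel.SITTING:
        key = ("sitting", seg.start)
        if key not in anchor_cache:
            anchor_cache[key] = (float(rng.uniform(80, 320)), FLOOR_Y - 5.0)
        return _to_pixels(_sitting_points(), anchor_cache[key], scale)
    if pose in (PoseLabel.LYING_IN_BED, PoseLabel.SLEEPING):
        anchor = _bed_anchor(script.bed_region, scale)
        pts = _lying_points()
        arr = _to_pixels(pts, anchor, scale)
        if pose is PoseLabel.LYING_IN_BED:
            # awake fidgeting: slow lateral shifting of the whole body
            arr[:, 0] += 0.04 * scale * seg.amplitude * math.sin(2 * math.pi * t / 20.0)
        return arr
    if pose is PoseLabel.FALLEN_ON_GROUND:
        key = ("fallen", seg.start)
        if key not in anchor_cache:
            anchor_cache[key] = (float(rng.uniform(40, 180)), float(rng.uniform(370, 430)))
        return _to_pixels(_lying_points(), anchor_cache[key], scale)
    raise ValueError(f"cannot synthesize frames for pose {pose}")


def generate_skeleton_sequence(script: ScenarioScript, fps: float = 10.0) -> list[FrameRecord]:
    """Render the script into per-frame skeletons at ``fps``.

    A 60 s script at 10 fps yields 600 frames.  Keypoint noise is isotropic
    Gaussian with sigma = noise_frac * torso length; occlusion drops a
    keypoint (confidence 0) with probability occlusion_prob.  The same seed
    always yields the identical stream.
    """
    rng = np.random.default_rng(script.seed)
    torso_px = 0.29 * script.scale
    frames: list[FrameRecord] = []
    anchor_cache: dict = {}
    for seg in script.segments:
        n = int(round((seg.end - seg.start) * fps))
        for k in range(n):
            t = seg.start + k / fps
            xy = _pose_pixels(PoseLabel(seg.pose), t, seg, script, anchor_cache, rng)
            if script.noise_frac > 0:
                xy = xy + rng.normal(0.0, script.noise_frac * torso_px, xy.shape)
            conf = rng.uniform(0.85, 1.0, len(xy))
            if script.occlusion_prob > 0:
                occl = rng.random(len(xy)) < script.occlusion_prob
                conf[occl] = 0.0
            arr = np.column_stack([xy, conf])
            sk = Skeleton.from_array(arr, timestamp=t, person_tag=script.subject_tag)
            frames.append(
                FrameRecord(timestamp=t, skeletons=(sk,), lighting_tag=script.lighting_at(t))
            )
    frames.sort(key=lambda f: f.timestamp)
    return frames


# ---------------------------------------------------------------------------
# Vitals
# ---------------------------------------------------------------------------

def generate_vitals(script: ScenarioScript, period: float = 60.0) -> VitalsSeries:
    """Wristband series at ``period`` s: heart rate = baseline + circadian
    term + noise, reduced by ``hr_sleep_drop`` with sleep_state raised
    inside scripted sleep intervals; dropouts blank whole records."""
    rng = np.random.default_rng(script.seed + 1)
    rows = []
    t = script.start
    while t < script.end:
        asleep = any(a <= t < b for a, b in script.sleep_intervals)
        if rng.random() < script.vitals_dropout:
            rows.append({"timestamp": t})
        else:
            hr = (
                script.baseline_hr
                + 3.0 * math.sin(2 * math.pi * (t % 86400.0) / 86400.0)
                + rng.normal(0.0, 1.5)
            )
            if asleep:
                hr -= script.hr_sleep_drop
            rows.append(
                {
                    "timestamp": t,
                    "heart_rate": max(hr, 30.0),
                    "spo2": float(np.clip(97.0 + rng.normal(0, 0.5), 90.0, 100.0)),
                    "systolic": 125.0 + rng.normal(0, 4.0),
                    "diastolic": 78.0 + rng.normal(0, 3.0),
                    "weight": 70.0 + rng.normal(0, 0.1),
                    "sleep_state": bool(asleep),
                    "sleep_hours": None,
                    "source": "wristband",
                }
            )
        t += period
    import pandas as pd

    return VitalsSeries(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Patient states
# ---------------------------------------------------------------------------

#: Default sampling priors: first (clinically stable) value of each variable
#: carries most of the mass, abnormal values are uncommon, severe ones rare —
#: the prevalence profile of a stable long-term-care ward.  Pass
#: priors="uniform" for uniform sampling over the value sets.
DEFAULT_PRIORS: dict[str, tuple[float, ...]] = {
    "MoveC": (0.42, 0.25, 0.20, 0.13),
    "RiskC": (0.38, 0.30, 0.20, 0.12),
    "Bedsores": (0.94, 0.06),
    "Diseases": (0.25, 0.15, 0.15, 0.20, 0.10, 0.15),
    "Med": (0.30, 0.15, 0.35, 0.20),
    "BMI": (0.582, 0.12, 0.12, 0.07, 0.07, 0.028, 0.01),
    "MoveH": (0.86, 0.06, 0.045, 0.035),
    "EatH": (0.62, 0.30, 0.08),
    "EatC": (0.55, 0.30, 0.15),
    "Bowel": (0.64, 0.06, 0.15, 0.15),
    "Sleep": (0.125, 0.25, 0.46, 0.15, 0.015),
    "Breath": (0.845, 0.08, 0.05, 0.025),
    "PL": (0.82, 0.10, 0.08),
    "BP": (0.50, 0.08, 0.27, 0.115, 0.035),
    "Temp": (0.90, 0.03, 0.04, 0.03),
    "Sat": (0.94, 0.06),
    "Urine": (0.72, 0.12, 0.11, 0.05),
    "Fluid": (0.94, 0.06),
    "Gly": (0.97, 0.03),
    "Con": (0.935, 0.04, 0.025),
    "Pain": (0.505, 0.25, 0.15, 0.085, 0.01),
}


def generate_patient_states(
    n: int,
    ruleset: RuleSet,
    seed: int = 0,
    priors: Union[str, dict, None] = None,
) -> list[tuple[PatientState, PlanAction]]:
    """Sample schema-valid states and label them with the rule engine.

    ``priors`` is None/"default" for the ward prevalence profile,
    "uniform" for uniform sampling, or a {variable: probabilities} dict.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if priors is None or priors == "default":
        pri = DEFAULT_PRIORS
    elif priors == "uniform":
        pri = {v: tuple([1.0 / len(vals)] * len(vals)) for v, vals in PATIENT_SCHEMA.items()}
    else:
        pri = dict(priors)
    out = []
    for _ in range(n):
        values = {}
        for var, vals in PATIENT_SCHEMA.items():
            p = np.asarray(pri[var], dtype=float)
            if len(p) != len(vals):
                raise ValueError(f"priors for {var!r} have wrong length")
            p = p / p.sum()
            values[var] = vals[int(rng.choice(len(vals), p=p))]
        state = PatientState(values=values, height=float(rng.uniform(1.50, 1.90)))
        action, _ = evaluate_rules(state, ruleset)
        out.append((state, action))
    return out


# ---------------------------------------------------------------------------
# Labelled skeletons for the posture benchmark
# ---------------------------------------------------------------------------

_STATIC_BUILDERS = (
    StaticPose.UPRIGHT,
    StaticPose.SITTING,
    StaticPose.LYING_LIKE,
    StaticPose.FALLEN_ON_GROUND,
)


def generate_labelled_skeletons(
    n_per_class: int,
    noise_frac: float = 0.0,
    occlusion_prob: float = 0.0,
    seed: int = 0,
    bed_region: tuple[tuple[float, float], ...] = DEFAULT_BED_REGION,
) -> list[tuple[Skeleton, StaticPose]]:
    """Single-frame benchmark: random placement, stature, and posture
    jitter per class; noise/occlusion as in the stream generator."""
    rng = np.random.default_rng(seed)
    out: list[tuple[Skeleton, StaticPose]] = []
    for label in _STATIC_BUILDERS:
        for i in range(n_per_class):
            scale = float(rng.uniform(120.0, 168.0))
            jitter = float(rng.uniform(-5.0, 5.0))
            if label is StaticPose.UPRIGHT:
                pts = _rotate(_standing_points(), float(rng.uniform(-6, 6)))
                anchor = (float(rng.uniform(60, 360)), FLOOR_Y)
            elif label is StaticPose.SITTING:
                pts = _rotate(_sitting_points(), float(rng.uniform(-4, 4)))
                anchor = (float(rng.uniform(60, 320)), FLOOR_Y - 5.0)
            elif label is StaticPose.LYING_LIKE:
                pts = _rotate(_lying_points(), jitter)
                anchor = (
                    float(rng.uniform(405, 455)),
                    float(rng.uniform(220, 270)),
                )
            else:  # fallen, on the open floor
                pts = _rotate(_lying_points(), jitter)
                anchor = (float(rng.uniform(40, 180)), float(rng.uniform(370, 430)))
            xy = _to_pixels(pts, anchor, scale)
            if noise_frac > 0:
                xy = xy + rng.normal(0.0, noise_frac * 0.29 * scale, xy.shape)
            conf = rng.uniform(0.85, 1.0, len(xy))
            if occlusion_prob > 0:
                conf[rng.random(len(xy)) < occlusion_prob] = 0.0
            sk = Skeleton.from_array(
                np.column_stack([xy, conf]), timestamp=float(i), person_tag="bench"
            )
            out.append((sk, label))
    return out


# ---------------------------------------------------------------------------
# Ward images for re-identification
# ---------------------------------------------------------------------------

_PATIENT_TEXTURES = {
    "First": ("grating", 0.0, 6.0),  # vertical stripes
    "Second": ("grating", 90.0, 6.0),  # horizontal stripes
    "Third": ("checker", 0.0, 8.0),
}
# The open-set class draws from several "unseen" texture families.
_NONE_TEXTURES = (
    ("grating", 45.0, 6.0),
    ("grating", 135.0, 7.0),
    ("rings", 0.0, 9.0),
    ("checker", 45.0, 12.0),
)


def _texture(kind: str, angle: float, period: float, size: int, phase: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    th = math.radians(angle)
    u = xx * math.cos(th) + yy * math.sin(th)
    v = -xx * math.sin(th) + yy * math.cos(th)
    if kind == "grating":
        tex = np.sin(2 * math.pi * u / period + phase)
    elif kind == "checker":
        tex = np.sign(np.sin(2 * math.pi * u / period + phase)) * np.sign(
            np.sin(2 * math.pi * v / period + phase)
        )
    elif kind == "rings":
        r = np.hypot(xx - size / 2, yy - size / 2)
        tex = np.sin(2 * math.pi * r / period + phase)
    else:
        raise ValueError(f"unknown texture kind {kind!r}")
    return tex


def generate_ward_images(
    identities: int = 3,
    per_class: int = 20,
    size: int = 64,
    noise: float = 6.0,
    seed: int = 0,
) -> list[tuple[np.ndarray, str]]:
    """Procedural (image, label) pairs for up to 3 patients + "None".

    Each identity wears a fixed texture rendered inside an elliptical
    silhouette over a varying background; None-class images draw from a
    pool of other textures.  Pixel-identical reproduction from the same
    seed.
    """
    if not 1 <= identities <= 3:
        raise ValueError("identities must be between 1 and 3")
    if per_class < 2:
        raise ValueError("per_class must be at least 2 to allow a train/test split")
    rng = np.random.default_rng(seed)
    labels = list(_PATIENT_TEXTURES)[:identities] + ["None"]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    mask = ((xx - size / 2) / (size * 0.36)) ** 2 + ((yy - size / 2) / (size * 0.44)) ** 2 <= 1.0
    out: list[tuple[np.ndarray, str]] = []
    for label in labels:
        for i in range(per_class):
            if label == "None":
                kind, angle, period = _NONE_TEXTURES[int(rng.integers(len(_NONE_TEXTURES)))]
            else:
                kind, angle, period = _PATIENT_TEXTURES[label]
            phase = float(rng.uniform(0, 2 * math.pi))
            contrast = float(rng.uniform(70, 100))
            tex = _texture(kind, angle, period, size, phase) * contrast
            # varying plain background with a gentle gradient
            g0 = float(rng.uniform(60, 180))
            gdir = rng.normal(size=2)
            gdir /= np.linalg.norm(gdir)
            background = g0 + (xx * gdir[0] + yy * gdir[1]) * float(rng.uniform(-0.3, 0.3))
            img = background.copy()
            img[mask] = 128.0 + tex[mask]
            img += rng.normal(0.0, noise, img.shape)
            out.append((np.clip(img, 0, 255).astype(np.uint8), label))
    return out


def write_ward_images(
    images: Sequence[tuple[np.ndarray, str]], out_dir: Union[str, Path]
) -> None:
    """Write PNGs in a label-subfolder layout."""
    from PIL import Image

    out_dir = Path(out_dir)
    counters: dict[str, int] = {}
    for img, label in images:
        sub = out_dir / label
        sub.mkdir(parents=True, exist_ok=True)
        k = counters.get(label, 0)
        counters[label] = k + 1
        Image.fromarray(img).save(sub / f"{label.lower()}_{k:03d}.png")
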