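"""Static posture classification of a single skeleton.

A skeleton is reduced to a handful of geometric features (torso inclination,
bounding-box aspect, hip flexion, normalized head height, detected keypoint
fraction) that are invariant to translation and uniform scaling, and then
classified into the coarse static classes upright / sitting /
fallen_on_ground / lying_like / unknown.  The upright and lying-like classes
are split into their final labels (walking vs standing, lying in bed vs
sleeping) by the temporal verification protocol, never statically.

Two classifiers are available behind one model handle:

* a transparent rule-based fallback over the features — auditable and
  requiring no training;
* the package's pre-pruned Gini decision tree trained on labelled examples.

Horizontal skeletons are disambiguated between lying-like and fallen by a
configurable "bed region" polygon per camera: a horizontal torso whose
bounding-box centre lies inside the bed polygon is lying-like, outside it is
fallen on the ground.  This spatial prior is the one deliberately
position-dependent ingredient; all other features are pose-intrinsic.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from shapely.geometry import Point, Polygon

from .core import DETECTION_THRESHOLD, Skeleton, StaticPose
from .tree import DecisionTree

__all__ = [
    "PoseFeatures",
    "PoseModel",
    "extract_features",
    "classify_static",
    "train_pose_model",
    "DEFAULT_BED_REGION",
]

#: Default bed polygon for the synthetic 640x480 scene, (x, y) pixel corners.
DEFAULT_BED_REGION: tuple[tuple[float, float], ...] = (
    (400.0, 160.0),
    (620.0, 160.0),
    (620.0, 330.0),
    (400.0, 330.0),
)

#: Severity-ordered classes: ties in a leaf resolve toward danger.
STATIC_CLASS_ORDER = [
    StaticPose.FALLEN_ON_GROUND.value,
    StaticPose.LYING_LIKE.value,
    StaticPose.SITTING.value,
    StaticPose.UPRIGHT.value,
]

FEATURE_NAMES = (
    "torso_angle",
    "bbox_aspect",
    "hip_knee_angle",
    "head_above_hips",
    "detected_fraction",
    "in_bed",
)


@dataclasses.dataclass(frozen=True)
class PoseFeatures:
    """Geometric skeleton features.

    torso_angle : degrees from vertical of the mid-shoulder -> mid-hip axis,
        folded into [0, 90] (0 = upright, 90 = horizontal).
    bbox_aspect : height/width of the detected-keypoint bounding box.
    hip_knee_angle : mean over sides (with hip and knee detected) of the
        angle at the hip between the torso axis and the thigh, degrees.
        180 = straight (standing), ~90 = seated flexion.
    head_above_hips : vertical offset of head above mid-hip, in torso
        lengths (positive = head higher in the image).
    detected_fraction : fraction of the 17 keypoints above the detection
        threshold.
    torso_length : pixels; the only non-scale-invariant feature.
    bbox_center : (x, y) pixels, used solely for the bed-region prior.
    reliable : False when fewer than 4 keypoints (or no shoulder/hip) were
        detected; unreliable features classify as unknown.
    """

    torso_angle: float
    bbox_aspect: float
    hip_knee_angle: float
    head_above_hips: float
    detected_fraction: float
    torso_length: float
    bbox_center: tuple[float, float]
    reliable: bool

    def vector(self, bed_region: Optional[Sequence[tuple[float, float]]]) -> np.ndarray:
        in_bed = 1.0 if (bed_region is not None and _in_polygon(self.bbox_center, bed_region)) else 0.0
        return np.array(
            [
                self.torso_angle,
                self.bbox_aspect,
                self.hip_knee_angle,
                self.head_above_hips,
                self.detected_fraction,
                in_bed,
            ]
        )


def _in_polygon(point: tuple[float, float], polygon: Sequence[tuple[float, float]]) -> bool:
    return Polygon(polygon).buffer(1e-9).contains(Point(*point))


def _angle_from_vertical(vec: np.ndarray) -> float:
    norm = float(np.hypot(*vec))
    if norm == 0:
        return 0.0
    cos = abs(vec[1]) / norm  # y axis points down the image
    return math.degrees(math.acos(min(1.0, cos)))


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = float(np.hypot(*u)), float(np.hypot(*v))
    if nu == 0 or nv == 0:
        return 180.0
    cos = float(np.dot(u, v)) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def extract_features(
    skeleton: Skeleton, threshold: float = DETECTION_THRESHOLD
) -> PoseFeatures:
    """Deterministic features; undetected landmarks are excluded from every
    mean and angle.  Fewer than 4 detected keypoints (or no detected
    shoulder or hip) flags the features unreliable rather than raising."""
    arr = skeleton.as_array()
    det = skeleton.detected_mask(threshold)
    names = np.array([kp.name for kp in skeleton.keypoints])

    def pts(*wanted: str) -> np.ndarray:
        mask = det & np.isin(names, wanted)
        return arr[mask, :2]

    detected_fraction = float(det.sum()) / len(det)
    xy = arr[det, :2]
    if len(xy) > 0:
        center = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        width = max(float(xy[:, 0].max() - xy[:, 0].min()), 1e-6)
        height = float(xy[:, 1].max() - xy[:, 1].min())
        bbox_aspect = height / width
    else:
        center, bbox_aspect = (0.0, 0.0), 0.0

    shoulders = pts("left_shoulder", "right_shoulder")
    hips = pts("left_hip", "right_hip")
    reliable = det.sum() >= 4 and len(shoulders) > 0 and len(hips) > 0
    if not reliable:
        return PoseFeatures(0.0, bbox_aspect, 180.0, 0.0, detected_fraction, 0.0, center, False)

    mid_shoulder = shoulders.mean(axis=0)
    mid_hip = hips.mean(axis=0)
    torso = mid_hip - mid_shoulder
    torso_length = float(np.hypot(*torso))
    torso_angle = _angle_from_vertical(torso)

    angles = []
    for side in ("left", "right"):
        hip = pts(f"{side}_hip")
        knee = pts(f"{side}_knee")
        if len(hip) and len(knee):
            angles.append(_angle_between(mid_shoulder - hip[0], knee[0] - hip[0]))
    hip_knee_angle = float(np.mean(angles)) if angles else 180.0

    head = pts("nose")
    if len(head) == 0:
        head = pts("left_eye", "right_eye", "left_ear", "right_ear")
    if len(head) > 0 and torso_length > 1e-9:
        head_above_hips = float(mid_hip[1] - head.mean(axis=0)[1]) / torso_length
    else:
        head_above_hips = 0.0

    return PoseFeatures(
        torso_angle=torso_angle,
        bbox_aspect=bbox_aspect,
        hip_knee_angle=hip_knee_angle,
        head_above_hips=head_above_hips,
        detected_fraction=detected_fraction,
        torso_length=torso_length,
        bbox_center=center,
        reliable=True,
    )


@dataclasses.dataclass
class PoseModel:
    """Handle over either the rule fallback or a trained tree.

    kind : "rules" or "tree".
    bed_region : polygon used for the lying vs fallen spatial prior.
    horizontal_angle / seated_angle : fallback thresholds in degrees.
    """

    kind: str = "rules"
    bed_region: tuple[tuple[float, float], ...] = DEFAULT_BED_REGION
    horizontal_angle: float = 50.0
    seated_angle: float = 130.0
    tree: Optional[DecisionTree] = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "bed_region": [list(p) for p in self.bed_region],
            "horizontal_angle": self.horizontal_angle,
            "seated_angle": self.seated_angle,
            "tree": self.tree.to_dict() if self.tree is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoseModel":
        return cls(
            kind=d["kind"],
            bed_region=tuple(tuple(p) for p in d["bed_region"]),
            horizontal_angle=d["horizontal_angle"],
            seated_angle=d["seated_angle"],
            tree=DecisionTree.from_dict(d["tree"]) if d.get("tree") else None,
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PoseModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def classify_static(
    features: PoseFeatures, model: Optional[PoseModel] = None
) -> tuple[StaticPose, float]:
    """Classify one skeleton's features into a static pose with confidence.

    Unreliable features always yield (unknown, 0).  With ``model=None`` or a
    "rules" model the transparent fallback is used; a "tree" model must be
    trained.
    """
    if model is None:
        model = PoseModel()
    if not features.reliable:
        return StaticPose.UNKNOWN, 0.0
    if model.kind == "tree":
        if model.tree is None or model.tree.root is None:
            raise RuntimeError("tree model is not trained")
        x = features.vector(model.bed_region)
        label = model.tree.predict_one(x)
        conf = float(model.tree.predict_proba_one(x).max())
        return StaticPose(label), conf
    # rule-based fallback
    conf = features.detected_fraction
    if features.torso_angle >= model.horizontal_angle:
        if _in_polygon(features.bbox_center, model.bed_region):
            return StaticPose.LYING_LIKE, conf
        return StaticPose.FALLEN_ON_GROUND, conf
    if features.hip_knee_angle <= model.seated_angle:
        return StaticPose.SITTING, conf
    return StaticPose.UPRIGHT, conf


def train_pose_model(
    labelled: Sequence[tuple[PoseFeatures, StaticPose]],
    max_depth: int = 4,
    min_samples_leaf: int = 6,
    bed_region: Sequence[tuple[float, float]] = DEFAULT_BED_REGION,
    seed: int = 0,
) -> PoseModel:
    """Train the tree-backed posture model on (features, label) pairs.

    Needs at least 10 examples spanning at least 2 classes; the fit is
    deterministic given data order and seed, and the model serializes to
    JSON and back without changing any prediction.
    """
    if len(labelled) < 10:
        raise ValueError(f"need at least 10 labelled examples, got {len(labelled)}")
    classes_present = {StaticPose(lbl).value for _, lbl in labelled}
    if len(classes_present) < 2:
        raise ValueError("training data contains a single class")
    bed = tuple(tuple(p) for p in bed_region)
    X = np.array([f.vector(bed) for f, _ in labelled])
    y = [StaticPose(lbl).value for _, lbl in labelled]
    tree = DecisionTree(
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        classes=STATIC_CLASS_ORDER,
        feature_names=list(FEATURE_NAMES),
        seed=seed,
    )
    tree.fit(X, y)
    return PoseModel(kind="tree", bed_region=bed, tree=tree)
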