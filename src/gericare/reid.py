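"""Bag-of-visual-words patient re-identification.

Local patch descriptors are extracted from an image (around Harris corners
by default, falling back to a dense grid on weakly textured images),
quantized against a K-means visual vocabulary, and pooled into an
L1-normalized word-frequency histogram.  A linear one-vs-rest maximum-margin
classifier over histograms assigns one of up to four identity classes:
three ward patients ("First", "Second", "Third") plus the open-set "None"
class absorbing staff, visitors, and anyone unknown.  As an additional
open-set guard, a prediction whose top margin falls below a configurable
threshold is forced to "None".

Everything is reproducible from (data, seed, params), and both the
vocabulary and the identity model serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from skimage.feature import corner_harris, corner_peaks
from sklearn.cluster import KMeans
from sklearn.svm import LinearSVC

from .preprocess import to_grayscale

__all__ = [
    "DetectorParams",
    "Vocabulary",
    "IdentityModel",
    "extract_descriptors",
    "build_vocabulary",
    "encode",
    "train_identifier",
    "predict_identity",
    "IDENTITY_CLASSES",
]

IDENTITY_CLASSES = ("First", "Second", "Third", "None")

NONE_CLASS = "None"


@dataclasses.dataclass(frozen=True)
class DetectorParams:
    """Descriptor extraction parameters.

    method : "corner" (Harris corners; falls back to the dense grid when
        fewer than ``min_descriptors`` corners are found) or "grid".
    patch_size : side of the square patch; the descriptor is the
        mean-subtracted, L2-normalized flattened patch.
    stride : dense-grid step in pixels.
    flat_tol : patches with standard deviation below this are skipped
        (a constant image yields no descriptors).
    """

    method: str = "corner"
    patch_size: int = 8
    stride: int = 8
    flat_tol: float = 1.0
    min_descriptors: int = 10
    max_corners: int = 200


def extract_descriptors(
    image: np.ndarray, params: DetectorParams = DetectorParams()
) -> np.ndarray:
    """(n, patch_size**2) descriptor array; n may be 0.  Deterministic."""
    gray = to_grayscale(np.asarray(image)).astype(float)
    p = params.patch_size
    if gray.shape[0] < p or gray.shape[1] < p:
        raise ValueError(f"image {gray.shape} smaller than patch size {p}")
    if params.method not in ("corner", "grid"):
        raise ValueError(f"unknown detector method {params.method!r}")
    descs: list[np.ndarray] = []
    if params.method == "corner":
        response = corner_harris(gray)
        peaks = corner_peaks(
            response, min_distance=max(1, p // 2), num_peaks=params.max_corners
        )
        half = p // 2
        for r, c in peaks:
            r0, c0 = r - half, c - half
            if r0 < 0 or c0 < 0 or r0 + p > gray.shape[0] or c0 + p > gray.shape[1]:
                continue
            d = _normalize_patch(gray[r0 : r0 + p, c0 : c0 + p], params.flat_tol)
            if d is not None:
                descs.append(d)
        if len(descs) >= params.min_descriptors:
            return np.array(descs)
        descs = []
    for r0 in range(0, gray.shape[0] - p + 1, params.stride):
        for c0 in range(0, gray.shape[1] - p + 1, params.stride):
            d = _normalize_patch(gray[r0 : r0 + p, c0 : c0 + p], params.flat_tol)
            if d is not None:
                descs.append(d)
    return np.array(descs) if descs else np.empty((0, p * p))


def _normalize_patch(patch: np.ndarray, flat_tol: float) -> Optional[np.ndarray]:
    flat = patch.ravel().astype(float)
    if flat.std() < flat_tol:
        return None
    flat = flat - flat.mean()
    return flat / np.linalg.norm(flat)


@dataclasses.dataclass
class Vocabulary:
    """K-means visual-word centroids in descriptor space."""

    centroids: np.ndarray  # (k, d)
    seed: int
    n_iter: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def to_dict(self) -> dict:
        return {
            "centroids": self.centroids.tolist(),
            "seed": self.seed,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(np.asarray(d["centroids"], dtype=float), d["seed"], d["n_iter"])

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Vocabulary":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_vocabulary(descriptors: np.ndarray, k: int = 64, seed: int = 0) -> Vocabulary:
    """Lloyd's K-means over the pooled descriptor set; deterministic given seed."""
    descriptors = np.asarray(descriptors, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if descriptors.ndim != 2 or descriptors.shape[0] < k:
        raise ValueError(
            f"need at least k={k} descriptors, got {descriptors.shape[0] if descriptors.ndim == 2 else 0}"
        )
    km = KMeans(n_clusters=k, n_init=4, random_state=seed, algorithm="lloyd")
    km.fit(descriptors)
    return Vocabulary(centroids=km.cluster_centers_.copy(), seed=seed, n_iter=int(km.n_iter_))


def encode(
    image: np.ndarray,
    vocabulary: Vocabulary,
    params: DetectorParams = DetectorParams(),
) -> np.ndarray:
    """L1-normalized word histogram of an image.

    Each descriptor goes to its nearest centroid (Euclidean; ties to the
    lowest index).  An image with no descriptors returns the all-zero
    sentinel histogram.
    """
    descs = extract_descriptors(image, params)
    hist = np.zeros(vocabulary.k)
    if len(descs) == 0:
        return hist
    d2 = ((descs[:, None, :] - vocabulary.centroids[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    for w in nearest:
        hist[w] += 1.0
    return hist / hist.sum()


@dataclasses.dataclass
class IdentityModel:
    """Linear OvR maximum-margin classifier over word histograms."""

    classes: tuple[str, ...]
    coef: np.ndarray  # (n_classes, k) or (1, k) for the binary case
    intercept: np.ndarray
    none_threshold: Optional[float] = None  # top margin below this -> "None"
    seed: int = 0

    def decision_scores(self, histogram: np.ndarray) -> np.ndarray:
        h = np.asarray(histogram, dtype=float)
        raw = self.coef @ h + self.intercept
        if len(self.classes) == 2:
            return np.array([-raw[0], raw[0]])
        return raw

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "none_threshold": self.none_threshold,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IdentityModel":
        return cls(
            classes=tuple(d["classes"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            none_threshold=d.get("none_threshold"),
            seed=d.get("seed", 0),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "IdentityModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_identifier(
    histograms: Sequence[np.ndarray],
    labels: Sequence[str],
    none_threshold: Optional[float] = None,
    seed: int = 0,
    C: float = 1.0,
) -> IdentityModel:
    """Fit the identity classifier on labelled histograms.

    At least 2 and at most 4 classes (three patients plus "None") are
    allowed.  Deterministic given seed.
    """
    labels = [str(l) for l in labels]
    present = sorted(set(labels))
    if not 2 <= len(present) <= 4:
        raise ValueError(f"need 2-4 classes, got {len(present)}: {present}")
    unknown = set(labels) - set(IDENTITY_CLASSES)
    if unknown:
        raise ValueError(f"labels outside the identity classes: {sorted(unknown)}")
    X = np.asarray(histograms, dtype=float)
    svm = LinearSVC(C=C, random_state=seed, max_iter=10000)
    svm.fit(X, labels)
    return IdentityModel(
        classes=tuple(svm.classes_),
        coef=svm.coef_.copy(),
        intercept=svm.intercept_.copy(),
        none_threshold=none_threshold,
        seed=seed,
    )


def predict_identity(
    histogram: np.ndarray, model: IdentityModel
) -> tuple[str, float]:
    """Predicted label and its margin score.

    When the model carries a ``none_threshold`` and the top margin falls
    below it, the open-set "None" label is returned instead.
    """
    scores = model.decision_scores(histogram)
    i = int(np.argmax(scores))
    label, top = model.classes[i], float(scores[i])
    if (
        model.none_threshold is not None
        and label != NONE_CLASS
        and top < model.none_threshold
    ):
        return NONE_CLASS, top
    return label, top
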