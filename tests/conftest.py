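"""Shared fixtures: small synthetic inputs built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gericare.careplan import demo_ruleset
from gericare.core import KEYPOINT_NAMES, Skeleton
from gericare.synthetic import _standing_points, _to_pixels


@pytest.fixture(scope="session")
def ruleset():
    return demo_ruleset()


def make_skeleton(
    xy: np.ndarray,
    confidence: float | np.ndarray = 1.0,
    timestamp: float = 0.0,
    person: str = "p",
) -> Skeleton:
    conf = np.broadcast_to(np.asarray(confidence, dtype=float), (len(KEYPOINT_NAMES),))
    arr = np.column_stack([np.asarray(xy, dtype=float), conf])
    return Skeleton.from_array(arr, timestamp=timestamp, person_tag=person)


@pytest.fixture
def standing_skeleton() -> Skeleton:
    """Noise-free upright skeleton standing on the open floor."""
    xy = _to_pixels(_standing_points(), (200.0, 460.0), 160.0)
    return make_skeleton(xy)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
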