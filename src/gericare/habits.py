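"""Multi-day movement-habit change detection.

Daily active hours are the sum of walking, sitting, and standing time
(lying, sleeping, and fallen time are excluded):

    ActH = Walking(hrs) + Sitting(hrs) + Standing(hrs)

The day-over-day percentage change Diff(a, b) = ((a - b) / b) * 100 is
compared against the threshold kth (default 12.5%): the habit has *slowed
down* when both consecutive diffs over the last three days are <= -kth,
*increased* when both are >= +kth, and is *unchanged* otherwise.  A diff
exactly at +-kth satisfies its inequality.  The verdict feeds the MoveH
variable of the patient state.

Division by zero is replaced by sentinels: Diff(a, 0) with a > 0 is +inf
(any activity after an inactive day is an unbounded increase) and
Diff(0, 0) is 0.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Optional

from .core import GericareError, PoseLabel
from .temporal import ActivityLedger

__all__ = [
    "HabitChange",
    "HabitVerdict",
    "DEFAULT_KTH",
    "daily_active_hours",
    "percent_diff",
    "classify_movement_change",
    "classify_from_ledger",
]

DEFAULT_KTH = 12.5  # percent

ACTIVE_POSES = (PoseLabel.WALKING, PoseLabel.SITTING, PoseLabel.STANDING)


class HabitChange(str, enum.Enum):
    UNCHANGED = "unchanged"
    SLOWED_DOWN = "slowed down"
    INCREASED = "increased"


@dataclasses.dataclass(frozen=True)
class HabitVerdict:
    """Verdict plus the two percentage diffs that produced it."""

    value: HabitChange
    diffs: tuple[float, float]
    insufficient_data: bool = False


class MissingDayError(GericareError, KeyError):
    pass


def daily_active_hours(ledger: ActivityLedger, day: str) -> float:
    """Sum of walking + sitting + standing hours for one calendar day."""
    if day not in ledger.days:
        raise MissingDayError(f"day {day} absent from ledger")
    return sum(ledger.hours(day, p) for p in ACTIVE_POSES)


def percent_diff(a: float, b: float) -> float:
    """((a - b) / b) * 100, with sentinels for b == 0."""
    if b == 0:
        if a == 0:
            return 0.0
        return math.inf if a > 0 else -math.inf
    return ((a - b) / b) * 100.0


def classify_movement_change(
    acth: tuple[Optional[float], Optional[float], Optional[float]],
    kth: float = DEFAULT_KTH,
) -> HabitVerdict:
    """Classify the change from three daily active-hour values.

    ``acth`` is ordered most recent first: (day m-1, day m-2, day m-3).
    A missing day yields "unchanged" with the insufficient-data flag set.
    """
    h1, h2, h3 = acth
    if h1 is None or h2 is None or h3 is None:
        return HabitVerdict(HabitChange.UNCHANGED, (math.nan, math.nan), True)
    d12 = percent_diff(h1, h2)
    d23 = percent_diff(h2, h3)
    if d12 <= -kth and d23 <= -kth:
        value = HabitChange.SLOWED_DOWN
    elif d12 >= kth and d23 >= kth:
        value = HabitChange.INCREASED
    else:
        value = HabitChange.UNCHANGED
    return HabitVerdict(value, (d12, d23))


def classify_from_ledger(
    ledger: ActivityLedger, day: str, kth: float = DEFAULT_KTH
) -> HabitVerdict:
    """Verdict for calendar day ``day`` using the three preceding days'
    active hours (m-1, m-2, m-3 relative to ``day``)."""
    from datetime import date, timedelta

    d = date.fromisoformat(day)
    vals: list[Optional[float]] = []
    for back in (1, 2, 3):
        key = (d - timedelta(days=back)).isoformat()
        try:
            vals.append(daily_active_hours(ledger, key))
        except MissingDayError:
            vals.append(None)
    return classify_movement_change((vals[0], vals[1], vals[2]), kth=kth)
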