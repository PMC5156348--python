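"""Domain model for coded two-parent nest behaviour and effort metrics.

Time is measured in real-valued seconds since local midnight.  Behavioural
state intervals are half-open ``[start, end)``: an instantaneous boundary
point belongs to the later window.  Two states are coded per parent:
``care`` (sitting on / in body contact with eggs or nestlings) and
``inside`` (in the nest box but not in the care posture).  *Attendance* is
the union of the two.  Joint metrics intersect the two parents' interval
sets; total metrics take their union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import intervals as iv
from .intervals import Interval, IntervalSet

PARENTS = ("male", "female")
STATES = ("care", "inside")
STAGES = ("incubation", "provisioning")

# canonical recording spans (seconds since midnight)
FULL_DAY = (25200.0, 68400.0)      # 07:00-19:00
MIDDAY_3H = (36000.0, 46800.0)     # 10:00-13:00

DURATION_METRICS = (
    "male_care", "female_care",
    "male_attendance", "female_attendance",
    "joint_care", "joint_attendance",
    "total_care", "total_attendance",
)
METRICS = DURATION_METRICS + ("prop_male_feedings",)

#: metrics whose rows are individual parents rather than nests
INDIVIDUAL_METRICS = ("male_care", "female_care", "male_attendance", "female_attendance")


class UnsupportedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class StateInterval:
    """One coded behavioural bout for one parent."""

    parent: str
    state: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.parent not in PARENTS:
            raise ValueError(f"unknown parent {self.parent!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.end > self.start:
            raise iv.IntervalError(
                f"StateInterval({self.parent}, {self.state}) has end <= start "
                f"({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class FeedingEvent:
    """One regurgitation bout (point event)."""

    parent: str
    time: float

    def __post_init__(self) -> None:
        if self.parent not in PARENTS:
            raise ValueError(f"unknown parent {self.parent!r}")


@dataclass
class NestRecording:
    """All coded intervals and feeding events for one nest on one day."""

    nest_id: str
    stage: str
    stage_day: int
    record_start: float
    record_end: float
    intervals: List[StateInterval] = field(default_factory=list)
    feedings: List[FeedingEvent] = field(default_factory=list)
    gaps: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"{self.nest_id}: unknown stage {self.stage!r}")
        if not self.record_end > self.record_start:
            raise ValueError(f"{self.nest_id}: record_end <= record_start")
        for si in self.intervals:
            if si.start < self.record_start or si.end > self.record_end:
                raise ValueError(
                    f"{self.nest_id} day {self.stage_day}: interval "
                    f"({si.start}, {si.end}) outside recording span"
                )
        for fe in self.feedings:
            if not (self.record_start <= fe.time <= self.record_end):
                raise ValueError(
                    f"{self.nest_id} day {self.stage_day}: feeding at {fe.time} "
                    "outside recording span"
                )
        self.gaps = iv.normalize(self.gaps, context=f"gaps of {self.nest_id}")
        for s, e in self.gaps:
            if s < self.record_start or e > self.record_end:
                raise ValueError(f"{self.nest_id}: gap ({s}, {e}) outside span")

    @property
    def span(self) -> Interval:
        return (self.record_start, self.record_end)

    def track(self, parent: str, state: str) -> IntervalSet:
        """Normalized interval set for one parent and state."""
        raw = [(si.start, si.end) for si in self.intervals
               if si.parent == parent and si.state == state]
        return iv.normalize(raw, context=f"{self.nest_id}/{parent}/{state}")


def normalize_track(track: Sequence) -> IntervalSet:
    """Normalize a single-parent single-state track into a canonical set.

    Accepts ``StateInterval`` objects or bare ``(start, end)`` pairs.
    """
    pairs = [(t.start, t.end) if isinstance(t, StateInterval) else t for t in track]
    return iv.normalize(pairs)


def metric_intervals(rec: NestRecording, metric: str) -> IntervalSet:
    """Interval set realizing a duration metric on one recording.

    Individual metrics return the parent's normalized track (attendance is
    care ∪ inside); ``joint_*`` intersects and ``total_*`` unions the two
    parents' sets.
    """
    if metric == "prop_male_feedings":
        raise UnsupportedMetricError("prop_male_feedings is not a duration metric")
    if metric not in DURATION_METRICS:
        raise UnsupportedMetricError(f"unknown metric {metric!r}")
    scope, behaviour = metric.split("_", 1)

    def parent_set(parent: str) -> IntervalSet:
        if behaviour == "care":
            return rec.track(parent, "care")
        return iv.union(rec.track(parent, "care"), rec.track(parent, "inside"))

    if scope in PARENTS:
        return parent_set(scope)
    male, female = parent_set("male"), parent_set("female")
    if scope == "joint":
        return iv.intersect(male, female)
    return iv.union(male, female)  # total


@dataclass(frozen=True)
class WindowDuration:
    occupied: float
    observable: float
    missing: bool


def duration_in_window(
    intervals: Sequence[Interval],
    window: Interval,
    gaps: Sequence[Interval] = (),
    *,
    min_observable_frac: float = 0.95,
) -> WindowDuration:
    """Occupied vs observable seconds of an interval set inside a window.

    Footage gaps are removed from both numerator and denominator.  A window
    whose observable time falls below ``min_observable_frac`` of its nominal
    width is flagged missing (the caller decides whether to drop it).
    """
    visible = iv.subtract([window], list(gaps))
    observable = iv.total_length(visible)
    occupied = iv.total_length(iv.intersect(iv.clip(list(intervals), window), visible))
    width = window[1] - window[0]
    missing = observable < min_observable_frac * width or observable == 0.0
    return WindowDuration(occupied, observable, missing)


def proportion_male_feedings(rec: NestRecording, window: Optional[Interval] = None) -> float:
    """Male feeding bouts over all feeding bouts within a window.

    Returns NaN when no feedings fall in the window.  Only defined for
    provisioning recordings.
    """
    if rec.stage != "provisioning":
        raise UnsupportedMetricError(
            f"{rec.nest_id}: proportion of male feedings requires provisioning stage"
        )
    if window is None:
        window = rec.span
    counts: Dict[str, int] = {"male": 0, "female": 0}
    for fe in rec.feedings:
        if window[0] <= fe.time < window[1]:
            counts[fe.parent] += 1
    total = counts["male"] + counts["female"]
    if total == 0:
        return math.nan
    return counts["male"] / total
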