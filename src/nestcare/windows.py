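"""Sampling-window partitioning and effort-matrix assembly.

A full-day 07:00-19:00 recording tiles into 12 one-hour or 4 three-hour
windows; effort in each window is the proportion of observable time the
metric's behaviour occupied (or, for the feeding metric, the male share of
feeding bouts).  Matrices have one row per nest for joint/total metrics and
one row per parent for individual metrics, so row identity can feed nested
random terms downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import ethogram as eth
from .ethogram import NestRecording
from .intervals import Interval

HOUR = 3600.0


class WindowingError(ValueError):
    pass


def make_windows(rec: NestRecording, width_hours: float) -> List[Interval]:
    """Consecutive half-open windows tiling the recording span.

    ``width_hours`` must divide the span exactly.
    """
    span = rec.record_end - rec.record_start
    width = width_hours * HOUR
    n = span / width
    if abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise WindowingError(
            f"window width {width_hours}h does not divide the {span / HOUR}h span"
        )
    n = int(round(n))
    return [
        (rec.record_start + i * width, rec.record_start + (i + 1) * width)
        for i in range(n)
    ]


def window_effort(rec: NestRecording, metric: str, window: Interval,
                  *, min_observable_frac: float = 0.95) -> float:
    """Effort proportion for one metric in one window; NaN when missing."""
    if metric == "prop_male_feedings":
        return eth.proportion_male_feedings(rec, window)
    ivset = eth.metric_intervals(rec, metric)
    d = eth.duration_in_window(ivset, window, rec.gaps,
                               min_observable_frac=min_observable_frac)
    if d.missing:
        return math.nan
    return d.occupied / d.observable


@dataclass
class EffortMatrix:
    """Individuals x windows matrix of effort proportions for one metric."""

    metric: str
    window_width: float  # hours
    values: pd.DataFrame  # index: nest_id or (nest_id, parent); columns: window start s

    @property
    def group_sizes(self) -> pd.Series:
        return self.values.notna().sum(axis=1)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for key, row in self.values.iterrows():
            if isinstance(key, tuple):
                nest_id, parent = key
            else:
                nest_id, parent = key, ""
            for j, (start, val) in enumerate(row.items()):
                rows.append({
                    "metric": self.metric, "nest_id": nest_id, "parent": parent,
                    "window_index": j, "window_start_s": float(start), "value": val,
                })
        return pd.DataFrame(rows)


def _row_key(rec: NestRecording, metric: str):
    if metric in eth.INDIVIDUAL_METRICS:
        return (rec.nest_id, metric.split("_", 1)[0])
    return rec.nest_id


def effort_matrix(recs: Sequence[NestRecording], metric: str, width_hours: float,
                  *, min_observable_frac: float = 0.95) -> EffortMatrix:
    """Assemble the per-window effort matrix for one metric.

    All recordings must share stage and stage_day (one matrix per day, as
    the repeatability analyses require).
    """
    recs = list(recs)
    if not recs:
        raise WindowingError("no recordings supplied")
    stages = {(r.stage, r.stage_day) for r in recs}
    if len(stages) > 1:
        raise WindowingError(f"recordings mix stage/day combinations: {sorted(stages)}")
    data = {}
    columns: Optional[List[float]] = None
    for rec in recs:
        wins = make_windows(rec, width_hours)
        starts = [w[0] for w in wins]
        if columns is None:
            columns = starts
        elif starts != columns:
            raise WindowingError("recordings have inconsistent window grids")
        data[_row_key(rec, metric)] = [
            window_effort(rec, metric, w, min_observable_frac=min_observable_frac)
            for w in wins
        ]
    values = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    return EffortMatrix(metric=metric, window_width=width_hours, values=values)


def daily_effort(rec: NestRecording, metric: str,
                 *, min_observable_frac: float = 0.0) -> float:
    """Effort proportion over the whole observable recording."""
    return window_effort(rec, metric, rec.span,
                         min_observable_frac=min_observable_frac)


def stage_effort_matrix(recs: Sequence[NestRecording], metric: str,
                        window: Interval = eth.MIDDAY_3H) -> EffortMatrix:
    """Individuals x stage-days matrix from mid-day 3h samples.

    Each column is a stage_day; cell = effort in the 10:00-13:00 window of
    that day's recording.  Used for within-stage (across-days) repeatability.
    """
    recs = list(recs)
    if not recs:
        raise WindowingError("no recordings supplied")
    days = sorted({r.stage_day for r in recs})
    data: dict = {}
    for rec in recs:
        if rec.record_start > window[0] or rec.record_end < window[1]:
            raise WindowingError(
                f"{rec.nest_id} day {rec.stage_day}: recording does not cover "
                f"the {window} window"
            )
        key = _row_key(rec, metric)
        row = data.setdefault(key, {d: math.nan for d in days})
        row[rec.stage_day] = window_effort(rec, metric, window)
    values = pd.DataFrame.from_dict(data, orient="index")[days]
    return EffortMatrix(metric=metric, window_width=(window[1] - window[0]) / HOUR,
                        values=values)
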