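"""Readers and writers for the ethogram CSV formats.

The long event-log CSV has one row per coded bout or feeding, with columns
``nest_id, stage, stage_day, parent, record_type, state, start_s, end_s``.
``record_type`` is ``state`` (behavioural bout; ``state`` column filled,
both times set), ``feed`` (point event; ``end_s`` empty) or ``span`` (one
per recording, carrying the recording's start and end).  Footage gaps live
in a sidecar CSV with columns ``nest_id, stage, stage_day, start_s, end_s``.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .ethogram import FeedingEvent, NestRecording, StateInterval

EVENT_COLUMNS = ["nest_id", "stage", "stage_day", "parent", "record_type",
                 "state", "start_s", "end_s"]
GAP_COLUMNS = ["nest_id", "stage", "stage_day", "start_s", "end_s"]


class CorpusFormatError(ValueError):
    pass


def write_corpus(recs: Sequence[NestRecording], events_path, gaps_path=None) -> None:
    """Write recordings to the long event CSV (and optional gap sidecar)."""
    events_path = Path(events_path)
    with events_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for rec in recs:
            base = [rec.nest_id, rec.stage, rec.stage_day]
            w.writerow(base + ["", "span", "", repr(rec.record_start),
                               repr(rec.record_end)])
            for si in rec.intervals:
                w.writerow(base + [si.parent, "state", si.state,
                                   repr(si.start), repr(si.end)])
            for fe in rec.feedings:
                w.writerow(base + [fe.parent, "feed", "", repr(fe.time), ""])
    if gaps_path is not None:
        with Path(gaps_path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(GAP_COLUMNS)
            for rec in recs:
                for s, e in rec.gaps:
                    w.writerow([rec.nest_id, rec.stage, rec.stage_day,
                                repr(s), repr(e)])


def read_corpus(events_path, gaps_path=None) -> List[NestRecording]:
    """Read and validate a corpus from the long event CSV.

    Rows are grouped by (nest_id, stage, stage_day); each group must carry
    exactly one ``span`` row.  Malformed rows raise
    :class:`CorpusFormatError` with the offending line number; overlapping
    same-state bouts are legal (normalized downstream with a warning at
    validation).
    """
    events_path = Path(events_path)
    groups: Dict[Tuple[str, str, int], dict] = {}

    def group(key):
        return groups.setdefault(key, {"span": None, "intervals": [],
                                       "feedings": []})

    with events_path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != EVENT_COLUMNS:
            raise CorpusFormatError(
                f"{events_path}: expected header {EVENT_COLUMNS}, "
                f"got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (row["nest_id"], row["stage"], int(row["stage_day"]))
                g = group(key)
                rtype = row["record_type"]
                if rtype == "span":
                    if g["span"] is not None:
                        raise CorpusFormatError("duplicate span row")
                    g["span"] = (float(row["start_s"]), float(row["end_s"]))
                elif rtype == "state":
                    start, end = float(row["start_s"]), float(row["end_s"])
                    if end <= start:
                        raise CorpusFormatError(
                            f"state bout has end_s <= start_s ({start}, {end})")
                    g["intervals"].append(
                        StateInterval(row["parent"], row["state"], start, end))
                elif rtype == "feed":
                    g["feedings"].append(
                        FeedingEvent(row["parent"], float(row["start_s"])))
                else:
                    raise CorpusFormatError(f"unknown record_type {rtype!r}")
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"{events_path}:{lineno}: {exc}") from None
            except (KeyError, ValueError) as exc:
                raise CorpusFormatError(f"{events_path}:{lineno}: {exc}") from None

    gaps: Dict[Tuple[str, str, int], List[Tuple[float, float]]] = {}
    if gaps_path is not None and Path(gaps_path).exists():
        with Path(gaps_path).open(newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                try:
                    key = (row["nest_id"], row["stage"], int(row["stage_day"]))
                    gaps.setdefault(key, []).append(
                        (float(row["start_s"]), float(row["end_s"])))
                except (KeyError, ValueError) as exc:
                    raise CorpusFormatError(f"{gaps_path}:{lineno}: {exc}") from None

    out = []
    for key, g in sorted(groups.items()):
        nest_id, stage, stage_day = key
        if g["span"] is None:
            raise CorpusFormatError(
                f"{events_path}: no span row for {nest_id}/{stage}/day {stage_day}")
        out.append(NestRecording(
            nest_id=nest_id, stage=stage, stage_day=stage_day,
            record_start=g["span"][0], record_end=g["span"][1],
            intervals=g["intervals"], feedings=g["feedings"],
            gaps=gaps.get(key, [])))
    return out


def read_wide_tsv(path, *, nest_id: str, stage: str, stage_day: int) -> NestRecording:
    """Import a per-second wide table (time_s, male_state, female_state).

    State cells are ``care``, ``inside`` or empty (off nest); each row
    covers the second ``[time_s, time_s + 1)``.  Consecutive identical
    states are merged into bouts.
    """
    rows = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append((float(row["time_s"]),
                         row.get("male_state", ""), row.get("female_state", "")))
    if not rows:
        raise CorpusFormatError(f"{path}: empty wide table")
    rows.sort()
    intervals: List[StateInterval] = []
    for parent, col in (("male", 1), ("female", 2)):
        cur_state, cur_start, prev_t = None, None, None
        for r in rows:
            t, st = r[0], r[col] or None
            if st == cur_state and prev_t is not None and t == prev_t + 1:
                prev_t = t
                continue
            if cur_state is not None:
                intervals.append(StateInterval(parent, cur_state,
                                               cur_start, prev_t + 1))
            cur_state, cur_start, prev_t = st, t, t
            if st is None:
                cur_state = None
        if cur_state is not None:
            intervals.append(StateInterval(parent, cur_state, cur_start, prev_t + 1))
    return NestRecording(nest_id=nest_id, stage=stage, stage_day=stage_day,
                         record_start=rows[0][0], record_end=rows[-1][0] + 1,
                         intervals=intervals)


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    seed: Optional[int]
    inputs: List[str]
    outputs: List[str]
    config_hash: str = ""
    package_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def hash_config(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]
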