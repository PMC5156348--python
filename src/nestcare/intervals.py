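"""Exact algebra on sets of half-open real intervals.

An *interval set* is represented canonically as a list of ``(start, end)``
tuples that are sorted, pairwise disjoint and non-touching.  All operations
below accept any iterable of ``(start, end)`` pairs and return canonical
sets, so they compose freely.  Endpoints are floats (seconds); the algebra
is exact up to floating-point representation.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[float, float]
IntervalSet = List[Interval]


class IntervalError(ValueError):
    """Raised for degenerate or inverted intervals."""


def normalize(intervals: Iterable[Interval], *, context: str = "") -> IntervalSet:
    """Sort, validate and merge a collection of intervals.

    Touching or overlapping intervals are merged; the union of the input is
    preserved exactly.  Raises :class:`IntervalError` for any interval with
    ``end <= start``, naming ``context`` in the message.
    """
    items = []
    for iv in intervals:
        s, e = float(iv[0]), float(iv[1])
        if not e > s:
            where = f" in {context}" if context else ""
            raise IntervalError(f"interval ({s}, {e}){where} has end <= start")
        items.append((s, e))
    items.sort()
    merged: IntervalSet = []
    for s, e in items:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Sequence[Interval]) -> float:
    """Total measure of a canonical interval set."""
    return sum(e - s for s, e in intervals)


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> IntervalSet:
    """Intersection of two canonical interval sets (two-pointer sweep)."""
    out: IntervalSet = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def union(a: Iterable[Interval], b: Iterable[Interval]) -> IntervalSet:
    """Union of two interval sets."""
    return normalize(list(a) + list(b))


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> IntervalSet:
    """Set difference ``a \\ b`` of canonical interval sets."""
    out: IntervalSet = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Sequence[Interval], window: Interval) -> IntervalSet:
    """Restrict a canonical interval set to a half-open window."""
    return intersect(intervals, [window])
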