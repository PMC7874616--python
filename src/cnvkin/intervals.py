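"""Closed-interval arithmetic on 1-based inclusive coordinates.

Every function here treats an interval ``(start, end)`` as the set of
integer positions ``{start, ..., end}``; length is ``end - start + 1``.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def interval_length(start: int, end: int) -> int:
    """Inclusive length of [start, end]."""
    if end < start:
        raise ValueError(f"end < start: [{start}, {end}]")
    return end - start + 1


def intersection_length(s1: int, e1: int, s2: int, e2: int) -> int:
    """Number of positions shared by [s1,e1] and [s2,e2] (0 if disjoint)."""
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def gap_between(s1: int, e1: int, s2: int, e2: int) -> int:
    """Signed gap between two intervals: number of positions strictly between
    them; <= 0 when they touch or overlap."""
    if s1 > s2:
        s1, e1, s2, e2 = s2, e2, s1, e1
    return s2 - e1 - 1


def merge_union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint intervals.

    Touching intervals (gap 0) are coalesced.
    """
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            ps, pe = out[-1]
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def union_coverage_length(
    intervals: Iterable[tuple[int, int]], start: int, end: int
) -> int:
    """Number of positions of [start, end] covered by the union of intervals."""
    total = 0
    for s, e in merge_union(intervals):
        total += intersection_length(s, e, start, end)
    return total


def covered_fraction(
    start: int, end: int, intervals: Iterable[tuple[int, int]]
) -> float:
    """Fraction of [start, end] covered by the union of intervals."""
    return union_coverage_length(intervals, start, end) / interval_length(start, end)


def coverage_regions(
    intervals: Sequence[tuple[int, int]], min_depth: int
) -> list[tuple[int, int]]:
    """Maximal intervals where coverage depth by ``intervals`` is >= min_depth.

    Sweep-line over interval endpoints; O(n log n), exact at base resolution.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        events.append((s, +1))
        events.append((e + 1, -1))
    events.sort()
    out: list[tuple[int, int]] = []
    depth = 0
    region_start: int | None = None
    i = 0
    n = len(events)
    while i < n:
        pos = events[i][0]
        while i < n and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth >= min_depth and region_start is None:
            region_start = pos
        elif depth < min_depth and region_start is not None:
            out.append((region_start, pos - 1))
            region_start = None
    return out


def reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """min(o/len1, o/len2) where o is the shared length."""
    o = intersection_length(s1, e1, s2, e2)
    if o == 0:
        return 0.0
    return min(o / interval_length(s1, e1), o / interval_length(s2, e2))
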