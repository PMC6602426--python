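"""Half-open genomic interval algebra.

All intervals are 0-based half-open ``(start, end)`` tuples on the forward
strand. Input lists need not be sorted; outputs are sorted and merged.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or abutting intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two merged interval lists."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_all(interval_sets: Sequence[Sequence[Interval]]) -> list[Interval]:
    if not interval_sets:
        return []
    acc = merge(interval_sets[0])
    for ivs in interval_sets[1:]:
        acc = intersect(acc, ivs)
    return acc


def union_all(interval_sets: Sequence[Sequence[Interval]]) -> list[Interval]:
    flat = [iv for ivs in interval_sets for iv in ivs]
    return merge(flat)


def contains(intervals: Sequence[Interval], start: int, end: int) -> bool:
    """True iff [start, end) lies entirely within the merged coverage."""
    for s, e in merge(intervals):
        if s <= start and end <= e:
            return True
        if s > start:
            break
    return False


def overlaps(intervals: Sequence[Interval], start: int, end: int) -> bool:
    """True iff [start, end) overlaps any interval by at least 1 bp."""
    return any(s < end and start < e for s, e in intervals)
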