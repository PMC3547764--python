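"""Half-open interval arithmetic shared across the annotation stages."""

from __future__ import annotations

from typing import Iterable


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting [start, end) intervals into a sorted disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(
    minuend: Iterable[tuple[int, int]], subtrahend: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference minuend \\ subtrahend; both merged first, result sorted disjoint."""
    a = merge_intervals(minuend)
    b = merge_intervals(subtrahend)
    out: list[tuple[int, int]] = []
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


def complement_intervals(
    intervals: Iterable[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Complement of the interval set within [0, length)."""
    return subtract_intervals([(0, length)], intervals)


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)
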