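"""Interval arithmetic helpers on 0-based half-open coordinates."""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/touching [start, end) intervals into a sorted union."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def complement(intervals: Iterable[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Gaps of [0, length) not covered by any interval."""
    out: list[tuple[int, int]] = []
    pos = 0
    for s, e in merge_intervals(intervals):
        s, e = max(0, s), min(length, e)
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|); 1.0 means identical extent."""
    ov = overlap_len(a, b)
    la, lb = a[1] - a[0], b[1] - b[0]
    if la == 0 or lb == 0:
        return 0.0
    return min(ov / la, ov / lb)
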