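"""Exact integer interval arithmetic on (start, end) half-open pairs.

All functions operate on a single chromosome; callers group by chromosome
first. Lengths are in base pairs and exact (no floating point).
"""

from __future__ import annotations

import numpy as np


def merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping intervals as sorted disjoint intervals.

    Book-ended intervals ([0,10) and [10,20)) are coalesced.
    """
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def intersect_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total bp of intersection between two merged interval lists."""
    i = j = 0
    a, b = merge(a), merge(b)
    out = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def coverage_fraction(target: tuple[int, int], annotation: list[tuple[int, int]]) -> float:
    """Fraction of ``target`` covered by the union of ``annotation``."""
    s, e = target
    if e <= s:
        raise ValueError("empty target interval")
    return intersect_length([target], annotation) / (e - s)


def jaccard(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> float:
    """Base-pair Jaccard index |a ∩ b| / |a ∪ b| of two footprints."""
    la, lb = total_length(merge(a)), total_length(merge(b))
    if la == 0 and lb == 0:
        raise ValueError("Jaccard undefined for two empty footprints")
    inter = intersect_length(a, b)
    return inter / (la + lb - inter)


def random_intervals(
    rng: np.random.Generator,
    region: tuple[int, int],
    n: int,
    min_len: int,
    max_len: int,
) -> list[tuple[int, int]]:
    """n intervals with uniform start and uniform length inside region."""
    s0, e0 = region
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, e0 - s0)
        start = int(rng.integers(s0, max(e0 - length, s0) + 1))
        out.append((start, start + length))
    return out
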