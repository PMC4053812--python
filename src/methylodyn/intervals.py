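"""Arithmetic on half-open genomic intervals.

All functions take and return lists of (start, end) tuples with start < end,
0-based half-open, assumed to belong to a single chromosome. Inputs need not
be disjoint; outputs are sorted and non-overlapping.
"""

from __future__ import annotations

from typing import Iterable

Interval = tuple[int, int]


def merge(ivs: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching intervals."""
    ivs = sorted((int(s), int(e)) for s, e in ivs)
    out: list[Interval] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    return merge(list(a) + list(b))


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Parts of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
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
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def symmetric_difference(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Regions covered by exactly one of the two interval sets."""
    a, b = merge(a), merge(b)
    return merge(subtract(a, b) + subtract(b, a))


def gap_distance(a: Interval, b: Interval) -> int:
    """Edge-to-edge distance between two intervals; 0 if they overlap or touch."""
    if a[0] >= b[1]:
        return a[0] - b[1]
    if b[0] >= a[1]:
        return b[0] - a[1]
    return 0
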