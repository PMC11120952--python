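"""Small utilities on lists of 1-based inclusive intervals."""

from __future__ import annotations

import numpy as np

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals; touching intervals (e+1 == s) are merged."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Bases of `a` not covered by `b` (both need not be merged)."""
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] < cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] <= e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            k += 1
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


class IntervalSet:
    """Merged, sorted interval set supporting overlap and coverage queries."""

    def __init__(self, intervals: list[Interval]):
        m = merge(intervals)
        self.starts = np.array([s for s, _ in m], dtype=np.int64)
        self.ends = np.array([e for _, e in m], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    def overlaps(self, s: int, e: int) -> bool:
        """True iff [s, e] shares >=1 base with the set."""
        if len(self.starts) == 0:
            return False
        i = int(np.searchsorted(self.ends, s))  # first interval ending >= s
        return i < len(self.starts) and self.starts[i] <= e

    def covers(self, s: int, e: int) -> bool:
        """True iff every base of [s, e] lies in the set."""
        if len(self.starts) == 0:
            return False
        i = int(np.searchsorted(self.starts, s, side="right")) - 1
        return i >= 0 and self.ends[i] >= e
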