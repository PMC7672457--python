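"""Small interval-arithmetic helpers shared by the genomic modules.

All intervals are 0-based half-open (start, end) pairs; callers keep the
per-chromosome bookkeeping.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def merge_within_gap(
    intervals: Sequence[tuple[int, int]], gap: int = 0
) -> list[tuple[int, int]]:
    """Transitively merge intervals whose gap is <= ``gap``.

    gap 0 merges overlapping or abutting intervals.
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    out = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return [(s, e) for s, e in out]


class IntervalSet:
    """Query structure over a static set of (possibly overlapping) intervals."""

    def __init__(self, intervals: Sequence[tuple[int, int]]):
        ordered = sorted(intervals)
        self.starts = np.array([s for s, _ in ordered], dtype=np.int64)
        self.ends = np.array([e for _, e in ordered], dtype=np.int64)
        # running max of ends enables overlap queries on overlapping inputs
        self._maxend = (
            np.maximum.accumulate(self.ends) if len(self.ends) else self.ends
        )

    def __len__(self) -> int:
        return len(self.starts)

    def overlaps_any(self, start: int, end: int) -> bool:
        """True iff any stored interval shares >= 1 bp with [start, end)."""
        if len(self.starts) == 0:
            return False
        hi = int(np.searchsorted(self.starts, end, side="left"))
        if hi == 0:
            return False
        return bool(self._maxend[hi - 1] > start)
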