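"""Genomic interval algebra on 0-based half-open coordinates.

A thin, deterministic replacement for shelling out to BEDTools: merge,
intersect, subtract and closest over ``(chrom, start, end, payload)``
records.  All operations sort internally, so callers may pass intervals
in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

__all__ = ["Interval", "IntervalSet"]


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int
    payload: Any = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end < start: {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """Sorted collection of half-open intervals with BEDTools-style algebra."""

    def __init__(self, intervals: Iterable[Interval | tuple] = ()) -> None:
        items = []
        for iv in intervals:
            if not isinstance(iv, Interval):
                iv = Interval(*iv)
            items.append(iv)
        self.intervals: list[Interval] = sorted(items)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(i.chrom, i.start, i.end) for i in self.intervals] == [
            (i.chrom, i.start, i.end) for i in other.intervals
        ]

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.merge())

    def merge(self) -> "IntervalSet":
        """Union of the intervals: overlapping or book-ended runs collapse."""
        out: list[Interval] = []
        for iv in self.intervals:
            if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
                if iv.end > out[-1].end:
                    out[-1] = Interval(iv.chrom, out[-1].start, iv.end)
            else:
                out.append(Interval(iv.chrom, iv.start, iv.end))
        res = IntervalSet()
        res.intervals = out
        return res

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-pair intersection of the two merged sets."""
        a = self.merge().intervals
        b = other.merge().intervals
        out: list[Interval] = []
        i = j = 0
        while i < len(a) and j < len(b):
            x, y = a[i], b[j]
            if x.chrom != y.chrom:
                if x.chrom < y.chrom:
                    i += 1
                else:
                    j += 1
                continue
            s, e = max(x.start, y.start), min(x.end, y.end)
            if s < e:
                out.append(Interval(x.chrom, s, e))
            if x.end <= y.end:
                i += 1
            else:
                j += 1
        res = IntervalSet()
        res.intervals = out
        return res

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Parts of self not covered by other (both merged first)."""
        a = self.merge().intervals
        b = other.merge().intervals
        out: list[Interval] = []
        j = 0
        for x in a:
            cur = x.start
            # advance to the first b interval that could overlap x
            while j > 0 and (b[j - 1].chrom > x.chrom or
                             (b[j - 1].chrom == x.chrom and b[j - 1].end > x.start)):
                j -= 1
            k = j
            while k < len(b) and (b[k].chrom < x.chrom or
                                  (b[k].chrom == x.chrom and b[k].end <= x.start)):
                k += 1
            while k < len(b) and b[k].chrom == x.chrom and b[k].start < x.end:
                if b[k].start > cur:
                    out.append(Interval(x.chrom, cur, b[k].start))
                cur = max(cur, b[k].end)
                k += 1
            if cur < x.end:
                out.append(Interval(x.chrom, cur, x.end))
        res = IntervalSet()
        res.intervals = sorted(out)
        return res

    def closest(self, chrom: str, start: int, end: int) -> tuple[Interval | None, int]:
        """Nearest interval to [start, end) on chrom and the gap in bp.

        Distance is 0 when the query touches or overlaps the interval.
        Returns (None, -1) when no interval shares the chromosome.
        """
        best: Interval | None = None
        best_d = -1
        for iv in self.intervals:
            if iv.chrom != chrom:
                continue
            if iv.start < end and start < iv.end:
                d = 0
            elif iv.end <= start:
                d = start - iv.end
            else:
                d = iv.start - end
            if best is None or d < best_d or (d == best_d and (iv.start, iv.end) < (best.start, best.end)):
                best, best_d = iv, d
        return best, best_d

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in self.intervals)

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        return any(iv.overlaps(Interval(chrom, start, end)) for iv in self.intervals)

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end) covered by the (merged) set."""
        total = 0
        for iv in self.merge():
            if iv.chrom != chrom:
                continue
            total += max(0, min(iv.end, end) - max(iv.start, start))
        return total


def interval_ops(a: IntervalSet, b: IntervalSet | None, op: str, **kwargs) -> IntervalSet | tuple:
    """Dispatch helper mirroring the BEDTools verbs used across the pipeline."""
    if op == "merge":
        return a.merge()
    if op == "intersect":
        assert b is not None
        return a.intersect(b)
    if op == "subtract":
        assert b is not None
        return a.subtract(b)
    if op == "closest":
        return a.closest(kwargs["chrom"], kwargs["start"], kwargs["end"])
    raise ValueError(f"unknown interval op: {op!r}")
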