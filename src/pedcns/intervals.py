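"""Genomic interval algebra.

Every interval here is 0-based, half-open (BED convention). Variant
coordinates elsewhere in the package are 1-based inclusive (MAF convention)
and are converted exactly once, at the type boundary.

An :class:`IntervalSet` keeps, per chromosome, a sorted list of disjoint
intervals in which abutting intervals have been merged, so ``total_bp`` is
well defined and set operations are linear two-pointer sweeps. These sets
back the surveyed-region denominators of the TMB calculation and the
blacklist/arm arithmetic of the CNV consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Tuple


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp with *other*; 0 if on a different chromosome."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval
) -> Tuple[float, float]:
    """Overlap of *a* and *b* as a fraction of each interval's own length.

    Returns ``(overlap/|a|, overlap/|b|)``; ``(0.0, 0.0)`` when the
    intervals sit on different chromosomes or are disjoint. Two-caller CNV
    consensus requires both fractions to reach the reciprocal-overlap
    threshold (default 0.5).
    """
    ov = a.overlap_bp(b)
    if ov == 0:
        return (0.0, 0.0)
    return (ov / a.length, ov / b.length)


def _merge_sorted(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or abutting sorted (start, end) pairs."""
    merged: List[Tuple[int, int]] = []
    for start, end in pairs:
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


class IntervalSet:
    """A merged, sorted collection of disjoint intervals per chromosome."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {
            chrom: _merge_sorted(sorted(pairs))
            for chrom, pairs in sorted(by_chrom.items())
        }

    # -- basic accessors -------------------------------------------------

    @property
    def chroms(self) -> List[str]:
        return list(self._by_chrom)

    @property
    def total_bp(self) -> int:
        return sum(
            end - start
            for pairs in self._by_chrom.values()
            for start, end in pairs
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, pairs in self._by_chrom.items():
            for start, end in pairs:
                yield GenomicInterval(chrom, start, end)

    def __len__(self) -> int:
        return sum(len(pairs) for pairs in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, total_bp={self.total_bp})"

    # -- set operations --------------------------------------------------

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Membership test for a single 0-based position (binary search)."""
        pairs = self._by_chrom.get(chrom)
        if not pairs:
            return False
        lo, hi = 0, len(pairs)
        while lo < hi:
            mid = (lo + hi) // 2
            start, end = pairs[mid]
            if pos < start:
                hi = mid
            elif pos >= end:
                lo = mid + 1
            else:
                return True
        return False

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Intersection by a per-chromosome two-pointer sweep."""
        out: List[GenomicInterval] = []
        for chrom in self._by_chrom:
            a = self._by_chrom[chrom]
            b = other._by_chrom.get(chrom)
            if not b:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                start = max(a[i][0], b[j][0])
                end = min(a[i][1], b[j][1])
                if start < end:
                    out.append(GenomicInterval(chrom, start, end))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def overlap_bp(self, interval: GenomicInterval) -> int:
        """Total bp of this set falling inside *interval*."""
        pairs = self._by_chrom.get(interval.chrom, [])
        total = 0
        for start, end in pairs:
            if start >= interval.end:
                break
            total += max(0, min(end, interval.end) - max(start, interval.start))
        return total


def intersect_sets(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Functional alias for :meth:`IntervalSet.intersect`."""
    return a.intersect(b)
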