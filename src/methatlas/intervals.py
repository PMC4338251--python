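"""Genomic interval containers.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
No function in this package ever emits 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = ["GenomicInterval", "IntervalSet"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two regions share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    The set tracks whether it is *sorted* (by ``(chrom, start, end)``) and
    whether it is *merged* (sorted, pairwise disjoint, book-ended runs
    coalesced).  Fast overlap queries require a merged target set; :meth:`merge`
    produces one.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        *,
        assume_sorted: bool = False,
        assume_merged: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        if assume_merged:
            self.sorted = True
            self.merged = True
        elif assume_sorted:
            self.sorted = True
            self.merged = False
        else:
            self.sorted = self._check_sorted()
            self.merged = False
        self._index: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None

    # -- basics ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, sorted={self.sorted}, merged={self.merged})"

    def _check_sorted(self) -> bool:
        key = [(iv.chrom, iv.start, iv.end) for iv in self.intervals]
        return all(a <= b for a, b in zip(key, key[1:]))

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def sort(self) -> "IntervalSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(ivs, assume_sorted=True)

    def merge(self) -> "IntervalSet":
        """Coalesce overlapping and book-ended intervals into maximal runs.

        Idempotent: ``s.merge().merge() == s.merge()``.  Names and scores are
        dropped — a merged run has no single provenance.
        """
        out: list[GenomicInterval] = []
        cur: Optional[list] = None  # [chrom, start, end]
        for iv in self.sort():
            if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2]:
                cur[2] = max(cur[2], iv.end)
            else:
                if cur is not None:
                    out.append(GenomicInterval(cur[0], cur[1], cur[2]))
                cur = [iv.chrom, iv.start, iv.end]
        if cur is not None:
            out.append(GenomicInterval(cur[0], cur[1], cur[2]))
        return IntervalSet(out, assume_merged=True)

    def total_bp(self) -> int:
        """Total covered bases.  Requires a merged set (double-count hazard)."""
        if not self.merged:
            raise ValueError("total_bp requires a merged IntervalSet; call .merge()")
        return sum(iv.width for iv in self.intervals)

    # -- fast queries (merged target) -----------------------------------
    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._index is None:
            idx: dict[str, list[list[int]]] = {}
            for iv in self.intervals:
                idx.setdefault(iv.chrom, [[], []])
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
            self._index = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in idx.items()
            }
        return self._index

    def overlapping_range(self, chrom: str, start: int, end: int) -> range:
        """Indices (within this chromosome's arrays) of intervals overlapping
        ``[start, end)``.  Requires a merged (sorted, disjoint) set."""
        if not self.merged:
            raise ValueError("overlap queries require a merged IntervalSet")
        index = self._build_index()
        if chrom not in index:
            return range(0)
        starts, ends = index[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return range(lo, hi)

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return len(self.overlapping_range(iv.chrom, iv.start, iv.end)) > 0

    def overlap_any(self, queries: "IntervalSet") -> np.ndarray:
        """Boolean per query interval: does it overlap this (merged) set?"""
        return np.array([self.overlaps_interval(iv) for iv in queries], dtype=bool)

    def covered_bp_in(self, chrom: str, start: int, end: int) -> int:
        """Bases of ``[start, end)`` covered by this merged set."""
        index = self._build_index() if self.merged else None
        if index is None:
            raise ValueError("covered_bp_in requires a merged IntervalSet")
        if chrom not in index:
            return 0
        starts, ends = index[chrom]
        total = 0
        for i in self.overlapping_range(chrom, start, end):
            total += min(end, int(ends[i])) - max(start, int(starts[i]))
        return total

    def contains_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean per position: does it fall inside this merged set?"""
        if not self.merged:
            raise ValueError("contains_positions requires a merged IntervalSet")
        index = self._build_index()
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in index:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = index[chrom]
        k = np.searchsorted(starts, positions, side="right") - 1
        ok = k >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < ends[k[ok]]
        return out
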