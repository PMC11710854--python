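"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention) throughout the
library.  Conversion to or from 1-based closed conventions, where a file
format demands it, is confined to :mod:`sexchromtk.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "overlap_fraction",
    "bin_genome",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 on different sequences)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, joining neighbours separated by <= ``max_gap`` bp.

    The result is sorted by (chrom, start), covers every input base, and no
    two output intervals on the same sequence lie within ``max_gap`` of each
    other.  Idempotent and independent of input order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + max_gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def overlap_fraction(a: GenomicInterval, b: Sequence[GenomicInterval]) -> float:
    """Fraction of *a* covered by the union of *b* (in [0, 1])."""
    covered = sum(a.overlap(iv) for iv in merge_intervals(b))
    return covered / len(a)


def bin_genome(
    chrom_sizes: Mapping[str, int], window: int, step: int | None = None
) -> list[GenomicInterval]:
    """Tile each sequence with windows of ``window`` bp every ``step`` bp.

    Windows start at 0; the last window is truncated at the sequence end.  A
    sequence shorter than ``window`` yields a single truncated window.  With
    ``step < window`` the windows overlap by ``window - step`` bp (e.g. 5-kb
    windows with 2-kb overlap use step 3000).
    """
    if step is None:
        step = window
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (1 <= step <= window):
        raise ValueError("require 1 <= step <= window")
    out: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        if length < window:
            out.append(GenomicInterval(chrom, 0, length))
            continue
        n = math.ceil((length - window) / step) + 1
        for i in range(n):
            start = i * step
            out.append(GenomicInterval(chrom, start, min(start + window, length)))
    return out
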