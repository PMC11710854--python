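"""Windowed numeric tracks (depth, F/M ratio, identity, GC content).

A :class:`WindowTrack` pairs an ordered list of genomic windows with one
float per window; ``NaN`` marks a missing value (serialized as ``NA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

__all__ = ["WindowTrack"]


@dataclass
class WindowTrack:
    windows: list[GenomicInterval]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.windows) != len(self.values):
            raise ValueError(
                f"{len(self.windows)} windows but {len(self.values)} values"
            )
        prev: GenomicInterval | None = None
        for w in self.windows:
            if prev is not None and w.chrom == prev.chrom and w.start < prev.start:
                raise ValueError(
                    f"windows not sorted within {w.chrom} (at {w.start} after {prev.start})"
                )
            prev = w
        bad = ~(np.isfinite(self.values) | np.isnan(self.values))
        if bad.any():
            raise ValueError("track values must be finite or NaN (missing)")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def is_overlapping(self) -> bool:
        """True if any two successive windows on one sequence overlap."""
        for a, b in zip(self.windows, self.windows[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return True
        return False

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.windows:
            seen.setdefault(w.chrom, None)
        return list(seen)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.array([i for i, w in enumerate(self.windows) if w.chrom == chrom], dtype=int)

    def subset(self, chrom: str) -> "WindowTrack":
        idx = self.chrom_indices(chrom)
        return WindowTrack([self.windows[i] for i in idx], self.values[idx])

    def same_grid(self, other: "WindowTrack") -> bool:
        return self.windows == other.windows

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray) -> "WindowTrack":
        return WindowTrack(list(self.windows), np.asarray(values, dtype=float))
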