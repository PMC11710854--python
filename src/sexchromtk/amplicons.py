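"""Ampliconic-region detection from three evidence channels.

Sex-linked amplicons (near-identical gene-family expansions) are found
three ways and the results unioned:

1. **palindromes** — inverted self-alignment hits chained into arm pairs
   (>= 98% identity, arms >= 8 kb, spacer <= 500 kb, repeat content < 80%);
2. **tandem arrays** — 5-kb windows (2-kb overlap) of the repeat-masked
   sex-linked sequence with a non-self self-hit covering > 50% of the
   window at > 99% identity, merged, merged length >= 10 kb;
3. **depth excess** — non-PAR sex-linked 5-kb windows whose GC-corrected
   male depth reaches the autosomal level (amplicons collapsed during
   assembly carry the reads of all their copies), repeat content < 80%.

Genes with > 80% of their length inside the merged region set are called
ampliconic; olfactory/vomeronasal receptor families are excluded as
genome-wide amplifications that are not sex-specific.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, bin_genome, merge_intervals, overlap_fraction
from .io import AlignmentSegment
from .tracks import WindowTrack

__all__ = [
    "Palindrome",
    "AmpliconRegion",
    "AmpliconicGeneCall",
    "detect_palindromes",
    "detect_arrays",
    "gc_correct_depth",
    "autosome_reference",
    "detect_depth_amplicons",
    "merge_evidence",
    "call_ampliconic_genes",
    "DEFAULT_EXCLUSION_PATTERNS",
]

DEFAULT_EXCLUSION_PATTERNS = (r"^OR\d", r"^OLFR", r"^V[12]R", r"^VMN")


@dataclass(frozen=True)
class Palindrome:
    arm1: GenomicInterval
    arm2: GenomicInterval
    identity: float
    repeat_fraction: float

    @property
    def spacer(self) -> int:
        return self.arm2.start - self.arm1.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.arm1.chrom, self.arm1.start, self.arm2.end)


@dataclass(frozen=True)
class AmpliconRegion:
    interval: GenomicInterval
    evidence: frozenset[str]  # subset of {palindrome, array, depth}


@dataclass(frozen=True)
class AmpliconicGeneCall:
    gene: str
    interval: GenomicInterval
    overlap_fraction: float
    called: bool
    excluded_class: bool
    copy_number_estimate: int | None = None


# ---------------------------------------------------------------------------
# Channel 1: palindromes


def detect_palindromes(
    self_segments: Sequence[AlignmentSegment],
    repeats: Sequence[GenomicInterval],
    min_identity: float = 0.98,
    min_arm: int = 8_000,
    max_spacer: int = 500_000,
    max_repeat: float = 0.80,
    chain_gap: int = 2_000,
) -> list[Palindrome]:
    """Chain inverted self-hits into palindrome arm pairs and threshold.

    Only inverted-orientation segments with the query arm left of the
    target arm are considered (each palindrome appears once).  Segments
    whose arm projections are co-linear within ``chain_gap`` on both arms
    are chained; overlapping calls are deduplicated keeping the longer arm.
    """
    cands: list[list[AlignmentSegment]] = []
    for seg in sorted(
        (s for s in self_segments if s.strand == "-"
         and s.q_interval.chrom == s.t_interval.chrom
         and s.q_interval.start < s.t_interval.start),
        key=lambda s: (s.q_interval.chrom, s.q_interval.start),
    ):
        if seg.q_interval.end > seg.t_interval.start:
            warnings.warn(f"skipping self-overlapping inverted hit at {seg.q_interval}")
            continue
        placed = False
        for chain in cands:
            last = chain[-1]
            if (
                seg.q_interval.chrom == last.q_interval.chrom
                and 0 <= seg.q_interval.start - last.q_interval.end <= chain_gap
                and 0 <= last.t_interval.start - seg.t_interval.end <= chain_gap
            ):
                chain.append(seg)
                placed = True
                break
        if not placed:
            cands.append([seg])

    out: list[Palindrome] = []
    for chain in cands:
        arm1 = GenomicInterval(
            chain[0].q_interval.chrom,
            min(s.q_interval.start for s in chain),
            max(s.q_interval.end for s in chain),
        )
        arm2 = GenomicInterval(
            chain[0].t_interval.chrom,
            min(s.t_interval.start for s in chain),
            max(s.t_interval.end for s in chain),
        )
        total = sum(s.aligned_length for s in chain)
        ident = sum(s.identity * s.aligned_length for s in chain) / total
        if arm1.end > arm2.start:
            continue
        spacer = arm2.start - arm1.end
        span = GenomicInterval(arm1.chrom, arm1.start, arm2.end)
        rep = overlap_fraction(span, [r for r in repeats if r.chrom == span.chrom])
        if (
            ident >= min_identity
            and min(len(arm1), len(arm2)) >= min_arm
            and spacer <= max_spacer
            and rep < max_repeat
        ):
            out.append(Palindrome(arm1, arm2, ident, rep))

    # deduplicate overlapping palindromes, longer arms win
    out.sort(key=lambda p: -min(len(p.arm1), len(p.arm2)))
    kept: list[Palindrome] = []
    for p in out:
        if all(p.span.overlap(q.span) == 0 for q in kept):
            kept.append(p)
    kept.sort(key=lambda p: (p.arm1.chrom, p.arm1.start))
    return kept


# ---------------------------------------------------------------------------
# Channel 2: tandem arrays


def detect_arrays(
    chrom_sizes: Mapping[str, int],
    hits: Sequence[AlignmentSegment],
    window: int = 5_000,
    step: int = 3_000,
    min_rate: float = 0.50,
    min_identity: float = 0.99,
    min_merged: int = 10_000,
) -> list[GenomicInterval]:
    """Windows of the sex-linked sequence with a high-identity non-self
    self-hit covering more than half the window, merged into arrays.

    ``hits`` should come from a self-alignment of repeat-masked sequence;
    a hit whose target overlaps the window itself (the self locus) never
    supports that window.
    """
    windows = bin_genome(chrom_sizes, window, step)
    retained = [
        h for h in hits
        if h.identity > min_identity and h.q_interval.chrom in chrom_sizes
    ]
    candidates: list[GenomicInterval] = []
    for w in windows:
        for h in retained:
            if h.t_interval.overlap(w) > 0 and h.t_interval.chrom == w.chrom:
                continue  # self-locus hit
            if h.q_interval.overlap(w) > min_rate * len(w):
                candidates.append(w)
                break
    merged = merge_intervals(candidates, max_gap=0)
    return [iv for iv in merged if len(iv) >= min_merged]


# ---------------------------------------------------------------------------
# Channel 3: depth excess


def gc_correct_depth(
    depth: WindowTrack, gc: WindowTrack, bin_width: float = 0.01, min_bin: int = 20
) -> WindowTrack:
    """Remove GC bias by binned-median scaling.

    Windows are grouped into GC bins of ``bin_width``; each window is
    scaled by (global median / its bin median).  Bins with fewer than
    ``min_bin`` windows inherit the factor of the nearest populated bin,
    so sparse GC extremes are not rescaled by noise.
    """
    if not depth.same_grid(gc):
        raise ValueError("depth and GC tracks are on different window grids")
    vals = depth.values
    ok = ~np.isnan(vals) & ~np.isnan(gc.values)
    global_med = float(np.median(vals[ok]))
    bins = np.round(gc.values / bin_width).astype(int)
    factors: dict[int, float] = {}
    for b in np.unique(bins[ok]):
        sel = ok & (bins == b)
        if sel.sum() >= min_bin:
            med = float(np.median(vals[sel]))
            if med > 0:
                factors[b] = global_med / med
    if not factors:
        return depth.with_values(vals.copy())
    pop = np.array(sorted(factors))
    out = vals.copy()
    for b in np.unique(bins[ok]):
        nearest = int(pop[np.argmin(np.abs(pop - b))])
        sel = ok & (bins == b)
        out[sel] = vals[sel] * factors[nearest]
    return depth.with_values(out)


def autosome_reference(
    corrected: WindowTrack,
    autosome_regions: Sequence[GenomicInterval],
    stat: str = "mean",
) -> float:
    """Autosomal depth level of a corrected track (mean by default)."""
    merged = merge_intervals(autosome_regions)
    sel = [
        v for w, v in zip(corrected.windows, corrected.values)
        if not np.isnan(v) and any(r.contains(w) for r in merged)
    ]
    if not sel:
        raise ValueError("no autosomal windows in track")
    return float(np.mean(sel) if stat == "mean" else np.median(sel))


def detect_depth_amplicons(
    corrected_male: WindowTrack,
    autosome_ref: float,
    repeats: Sequence[GenomicInterval],
    sex_regions: Sequence[GenomicInterval],
    max_repeat: float = 0.80,
) -> list[GenomicInterval]:
    """Non-PAR sex-linked windows at or above the autosomal depth level
    (>= — a collapsed two-copy amplicon sits exactly at it), repeat
    content below ``max_repeat``, merged."""
    sex = merge_intervals(sex_regions)
    cands: list[GenomicInterval] = []
    for w, v in zip(corrected_male.windows, corrected_male.values):
        if np.isnan(v) or v < autosome_ref:
            continue
        if not any(r.contains(w) for r in sex):
            continue
        rep = overlap_fraction(w, [r for r in repeats if r.chrom == w.chrom])
        if rep < max_repeat:
            cands.append(w)
    return merge_intervals(cands, max_gap=0)


# ---------------------------------------------------------------------------
# Merge + gene calls


def merge_evidence(
    palindromes: Sequence[Palindrome],
    arrays: Sequence[GenomicInterval],
    depth_regions: Sequence[GenomicInterval],
) -> list[AmpliconRegion]:
    """Union of the three channels; each output interval is annotated with
    every channel contributing at least one base."""
    tagged: list[tuple[GenomicInterval, str]] = []
    tagged += [(p.span, "palindrome") for p in palindromes]
    tagged += [(iv, "array") for iv in arrays]
    tagged += [(iv, "depth") for iv in depth_regions]
    merged = merge_intervals([iv for iv, _ in tagged], max_gap=0)
    out = []
    for iv in merged:
        ev = frozenset(tag for src, tag in tagged if src.overlap(iv) > 0)
        assert ev, "merged amplicon with no contributing evidence"
        out.append(AmpliconRegion(iv, ev))
    return out


def call_ampliconic_genes(
    genes: Sequence[tuple[str, GenomicInterval]],
    regions: Sequence[AmpliconRegion],
    corrected_male: WindowTrack | None = None,
    autosome_ref: float | None = None,
    sex_regions: Sequence[GenomicInterval] | None = None,
    min_overlap: float = 0.80,
    exclusion_patterns: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS,
) -> list[AmpliconicGeneCall]:
    """Genes with > ``min_overlap`` of their length inside the amplicon set.

    Olfactory/vomeronasal receptor names are flagged and never called.
    When a corrected male depth track and autosomal reference are given,
    hemizygous-region genes get a copy-number estimate: the median
    corrected depth over the gene divided by the haploid autosomal level,
    rounded (labelled an estimate — assembly-collapsed copies only).
    """
    pats = [re.compile(p, re.IGNORECASE) for p in exclusion_patterns]
    region_ivs = [r.interval for r in regions]
    sex = merge_intervals(sex_regions) if sex_regions else []
    out: list[AmpliconicGeneCall] = []
    for name, iv in genes:
        frac = overlap_fraction(iv, region_ivs)
        excluded = any(p.search(name) for p in pats)
        called = frac > min_overlap and not excluded
        copy_est: int | None = None
        if corrected_male is not None and autosome_ref is not None and called:
            hemizygous = any(r.contains(iv) or r.overlap(iv) > 0 for r in sex)
            if hemizygous:
                depths = [
                    v for w, v in zip(corrected_male.windows, corrected_male.values)
                    if not np.isnan(v) and w.overlap(iv) > 0
                ]
                if depths:
                    copy_est = int(round(float(np.median(depths)) / (autosome_ref / 2.0)))
        out.append(AmpliconicGeneCall(name, iv, frac, called, excluded, copy_est))
    return out
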