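"""Sex-linkage calling from normalized female/male depth ratios.

The decision rule: scaffolds longer than 10 kb with over 60% of their 5-kb
windows at a normalized F/M coverage ratio inside [1.5, 2.5] are called
X-linked; inside [0.0, 0.3], Y-linked.  X-differentiated sequence is
diploid in females and haploid in males (ratio ~2), Y-differentiated
sequence is male-only (ratio ~0), and autosomes/PARs sit at ~1.  PAR
segments inside a sex-linked scaffold are delineated as maximal runs of
ratio-~1 windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval
from .tracks import WindowTrack

__all__ = [
    "ScaffoldCall",
    "normalize_depth",
    "fm_ratio",
    "classify_scaffolds",
    "delineate_par",
]


@dataclass(frozen=True)
class ScaffoldCall:
    scaffold: str
    length: int
    label: str  # X_linked | Y_linked | unclassified
    fraction_x_band: float
    fraction_y_band: float
    n_windows: int


def normalize_depth(track: WindowTrack, bin_width: float = 1.0) -> tuple[WindowTrack, float]:
    """Divide a depth track by its modal (peak) depth.

    The peak is the mean depth within the most populated histogram bin
    (``bin_width`` = 1x), restricted to bins above 0.25x the track maximum
    to skip the zero-inflated left tail from absent sequence.  The mode is
    used rather than the mean because hemizygous sex-linked windows skew
    the mean downward.  Diploid windows land near 1.0 after division.
    """
    vals = track.values[~np.isnan(track.values)]
    vals = vals[vals > 0]
    if len(vals) == 0:
        raise ValueError("cannot normalize an all-zero/missing depth track")
    lo = 0.25 * float(vals.max())
    edges = np.arange(0.0, float(vals.max()) + 2 * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    eligible = centers > lo
    if not eligible.any():
        eligible = np.ones_like(eligible, dtype=bool)
    best = int(np.flatnonzero(eligible)[np.argmax(counts[eligible])])
    in_bin = (vals >= edges[best]) & (vals < edges[best + 1])
    peak = float(vals[in_bin].mean())
    return track.with_values(track.values / peak), peak


def fm_ratio(
    female: WindowTrack,
    male: WindowTrack,
    pseudocount: float = 0.05,
    normalize: bool = True,
    cap: float = 10.0,
) -> WindowTrack:
    """Per-window (female + c)/(male + c) on peak-normalized depths.

    The pseudocount keeps ratios finite over female-absent Y windows; the
    cap bounds blow-ups where male depth is near zero.  Windows missing in
    either track stay missing.
    """
    if not female.same_grid(male):
        raise ValueError("female and male tracks are on different window grids")
    f = normalize_depth(female)[0].values if normalize else female.values
    m = normalize_depth(male)[0].values if normalize else male.values
    with np.errstate(invalid="ignore"):
        ratio = np.minimum((f + pseudocount) / (m + pseudocount), cap)
    return female.with_values(ratio)


def classify_scaffolds(
    ratios: WindowTrack,
    min_len: int = 10_000,
    min_frac: float = 0.60,
    x_band: tuple[float, float] = (1.5, 2.5),
    y_band: tuple[float, float] = (0.0, 0.3),
) -> list[ScaffoldCall]:
    """Label each scaffold X_linked / Y_linked / unclassified.

    Band endpoints are inclusive.  Scaffolds of at most ``min_len`` bp are
    left unclassified regardless of their windows; missing windows are
    excluded from the fraction denominators.
    """
    if min_frac > 0.5 and x_band[1] >= y_band[0] and y_band[1] >= x_band[0]:
        raise ValueError("X and Y bands overlap; calls would be ambiguous")
    calls: list[ScaffoldCall] = []
    for chrom in ratios.chroms():
        sub = ratios.subset(chrom)
        length = max(w.end for w in sub.windows)
        vals = sub.values[~np.isnan(sub.values)]
        n = len(vals)
        if n == 0:
            warnings.warn(f"{chrom}: no usable windows; left unclassified")
            calls.append(ScaffoldCall(chrom, length, "unclassified", 0.0, 0.0, 0))
            continue
        fx = float(np.mean((vals >= x_band[0]) & (vals <= x_band[1])))
        fy = float(np.mean((vals >= y_band[0]) & (vals <= y_band[1])))
        if length <= min_len:
            label = "unclassified"
        elif fx > min_frac:
            label = "X_linked"
        elif fy > min_frac:
            label = "Y_linked"
        else:
            label = "unclassified"
        calls.append(ScaffoldCall(chrom, length, label, fx, fy, n))
    return calls


def delineate_par(
    ratios: WindowTrack,
    scaffold: str,
    min_run: int = 10,
    par_band: tuple[float, float] = (0.75, 1.25),
    smooth_k: int = 5,
) -> list[GenomicInterval]:
    """Maximal runs of diploid-ratio windows within one scaffold.

    Windows are flagged when their ratio falls inside ``par_band``; a
    centered majority vote over ``smooth_k`` windows removes isolated
    flips; runs of at least ``min_run`` smoothed PAR windows are reported,
    snapped to window boundaries.
    """
    sub = ratios.subset(scaffold)
    if len(sub) == 0:
        raise ValueError(f"scaffold {scaffold!r} absent from ratio track")
    in_band = (
        (sub.values >= par_band[0]) & (sub.values <= par_band[1])
        & ~np.isnan(sub.values)
    ).astype(int)
    if smooth_k > 1:
        half = smooth_k // 2
        padded = np.pad(in_band, half, mode="edge")
        smoothed = np.array([
            int(padded[i:i + smooth_k].sum() * 2 > smooth_k)
            for i in range(len(in_band))
        ])
    else:
        smoothed = in_band
    out: list[GenomicInterval] = []
    i = 0
    while i < len(smoothed):
        if smoothed[i]:
            j = i
            while j < len(smoothed) and smoothed[j]:
                j += 1
            if j - i >= min_run:
                out.append(GenomicInterval(scaffold, sub.windows[i].start, sub.windows[j - 1].end))
            i = j
        else:
            i += 1
    return out
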