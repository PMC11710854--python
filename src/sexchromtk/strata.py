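"""Evolutionary strata: X/Y identity windows, JC69 divergence with
bootstrap confidence intervals, and stratum ages under a male-mutation-bias
rate model.

Recombination between a sex-chromosome pair stops in blocks ("strata");
each block's X/Y divergence ``div`` records when it stopped.  Under a
molecular clock the age is ``T = div / mu_XY``, where the X/Y divergence
rate differs from the autosomal one because mutation is male-biased: with
male-to-female rate ratio ``alpha`` and female rate ``mu_f``, per-year
branch rates are A: (1+alpha)/2 mu_f, X: (2+alpha)/3 mu_f, Y: alpha mu_f,
so the XY-to-autosome divergence-rate ratio is (2+4 alpha)/(3+3 alpha).

Divergence is estimated from concatenated non-coding, non-repetitive X/Y
alignment columns under the Jukes-Cantor (JC69) model,
``d = -(3/4) ln(1 - (4/3) p)``, with a percentile bootstrap over columns
for the 95% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, bin_genome
from .io import AlignmentSegment
from .tracks import WindowTrack

__all__ = [
    "RateModel",
    "PairwiseAlignment",
    "DivergenceEstimate",
    "StratumAgeEstimate",
    "identity_windows",
    "filter_y_segments",
    "jc69",
    "jc69_p",
    "bootstrap_divergence",
    "build_rate_model",
    "stratum_age",
]


@dataclass(frozen=True)
class RateModel:
    """Male-mutation-bias rate model linking autosomal and XY rates."""

    alpha: float          # male-to-female mutation-rate ratio
    mu_AA: float          # autosomal divergence rate, per site per year
    ratio: float          # (2 + 4*alpha) / (3 + 3*alpha)
    mu_XY: float          # ratio * mu_AA
    mu_f: float           # female rate, 2*mu_AA/(1+alpha)


def build_rate_model(alpha: float, mu_AA: float) -> RateModel:
    """XY divergence rate from male mutation bias.

    ``ratio`` is strictly increasing in alpha, bounded in (2/3, 4/3), and
    equals 1 exactly at alpha = 1 (no bias).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if mu_AA <= 0:
        raise ValueError("mu_AA must be positive")
    ratio = (2.0 + 4.0 * alpha) / (3.0 + 3.0 * alpha)
    return RateModel(alpha=alpha, mu_AA=mu_AA, ratio=ratio,
                     mu_XY=ratio * mu_AA, mu_f=2.0 * mu_AA / (1.0 + alpha))


@dataclass
class PairwiseAlignment:
    """Equal-length gapped X and Y strings with optional column mask.

    Valid columns are both non-gap, non-N and unmasked; only those enter
    mismatch counting and the bootstrap.
    """

    seq_x: str
    seq_y: str
    mask: np.ndarray | None = None  # True = excluded column

    def __post_init__(self) -> None:
        if len(self.seq_x) != len(self.seq_y):
            raise ValueError("aligned sequences must have equal length")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if len(self.mask) != len(self.seq_x):
                raise ValueError("mask length must match alignment length")

    def valid_columns(self) -> np.ndarray:
        x = np.frombuffer(self.seq_x.upper().encode("ascii"), dtype=np.uint8)
        y = np.frombuffer(self.seq_y.upper().encode("ascii"), dtype=np.uint8)
        bad = np.frombuffer(b"-N", dtype=np.uint8)
        ok = ~np.isin(x, bad) & ~np.isin(y, bad)
        if self.mask is not None:
            ok &= ~self.mask
        return ok

    def mismatch_indicator(self) -> np.ndarray:
        """Boolean mismatch flags over valid columns only."""
        x = np.frombuffer(self.seq_x.upper().encode("ascii"), dtype=np.uint8)
        y = np.frombuffer(self.seq_y.upper().encode("ascii"), dtype=np.uint8)
        ok = self.valid_columns()
        return (x != y)[ok]


@dataclass(frozen=True)
class DivergenceEstimate:
    p: float
    d: float
    n_columns: int
    ci: tuple[float, float]
    n_bootstrap: int
    seed: int
    n_discarded: int = 0


@dataclass(frozen=True)
class StratumAgeEstimate:
    T: float
    ci: tuple[float, float]


def jc69(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - (4/3) p)."""
    if not 0.0 <= p < 0.75:
        raise ValueError(f"mismatch proportion {p} outside [0, 0.75): JC69 saturated")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def jc69_p(d: float) -> float:
    """Expected mismatch proportion at JC69 divergence d (inverse of jc69)."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def bootstrap_divergence(
    aln: PairwiseAlignment,
    n_bootstrap: int = 1_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DivergenceEstimate:
    """JC69 divergence with a percentile bootstrap over alignment columns.

    Valid columns are resampled with replacement ``n_bootstrap`` times;
    replicates that saturate (p >= 3/4) are discarded with a warning and
    counted.  Deterministic under ``seed``.
    """
    mis = aln.mismatch_indicator()
    n = len(mis)
    if n == 0:
        raise ValueError("alignment has no valid columns")
    p = float(mis.mean())
    d = jc69(p)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    chunk = max(1, min(n_bootstrap, int(5e7 // max(n, 1)) or 1))
    got = 0
    while got < n_bootstrap:
        b = min(chunk, n_bootstrap - got)
        idx = rng.integers(0, n, size=(b, n))
        reps[got:got + b] = mis[idx].mean(axis=1)
        got += b
    sat = reps >= 0.75
    n_disc = int(sat.sum())
    if n_disc:
        warnings.warn(f"discarded {n_disc} saturated bootstrap replicates")
    reps = reps[~sat]
    d_reps = -0.75 * np.log(1.0 - 4.0 * reps / 3.0)
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(d_reps, [tail, 1.0 - tail])
    return DivergenceEstimate(p=p, d=d, n_columns=n, ci=(float(lo), float(hi)),
                              n_bootstrap=n_bootstrap, seed=seed, n_discarded=n_disc)


def stratum_age(est: DivergenceEstimate, model: RateModel) -> StratumAgeEstimate:
    """T = d / mu_XY, confidence limits scaled likewise (years)."""
    return StratumAgeEstimate(
        T=est.d / model.mu_XY,
        ci=(est.ci[0] / model.mu_XY, est.ci[1] / model.mu_XY),
    )


# ---------------------------------------------------------------------------
# Identity windows and Y-segment filtering


def identity_windows(
    segments: Sequence[AlignmentSegment],
    window: int = 1_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> WindowTrack:
    """Per-window X/Y identity along the query (X) coordinates.

    Window identity = matched bases / aligned columns intersecting the
    window; with only per-segment identities available, matches are
    distributed uniformly along each segment.  Uncovered windows are
    missing.
    """
    if chrom_sizes is None:
        chrom_sizes = {}
        for s in segments:
            c = s.q_interval.chrom
            chrom_sizes[c] = max(chrom_sizes.get(c, 0), s.q_interval.end)
    windows = bin_genome(chrom_sizes, window)
    matched = np.zeros(len(windows))
    columns = np.zeros(len(windows))
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    for s in segments:
        idxs = by_chrom.get(s.q_interval.chrom, ())
        for i in idxs:
            ov = windows[i].overlap(s.q_interval)
            if ov > 0:
                # segment coordinates are ungapped on the query; scale aligned
                # columns by the covered fraction of the query span
                frac = ov / len(s.q_interval)
                cols = frac * s.aligned_length
                columns[i] += cols
                ident = (s.matches / s.aligned_length
                         if s.matches is not None else s.identity)
                matched[i] += cols * ident
    with np.errstate(invalid="ignore"):
        values = np.where(columns > 0, matched / np.maximum(columns, 1e-12), np.nan)
    return WindowTrack(windows, values)


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def filter_y_segments(
    xy_segments: Sequence[AlignmentSegment],
    y_vs_other_segments: Sequence[AlignmentSegment],
    min_reciprocal: float = 0.5,
) -> list[AlignmentSegment]:
    """Drop X/Y blocks whose Y span aligns better elsewhere.

    An X/Y segment (target = Y span) is removed iff some autosome/PAR hit
    of the same Y span (query = Y span, >= 50% reciprocal overlap) has
    *strictly* higher identity and *strictly* longer aligned length; ties
    keep the segment.
    """
    kept: list[AlignmentSegment] = []
    for seg in xy_segments:
        y_span = seg.t_interval
        beaten = any(
            _reciprocal_overlap(y_span, other.q_interval) >= min_reciprocal
            and other.identity > seg.identity
            and other.aligned_length > seg.aligned_length
            for other in y_vs_other_segments
        )
        if not beaten:
            kept.append(seg)
    return kept
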