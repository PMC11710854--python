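"""Synthetic genomes with planted ground truth for offline pipeline testing.

The generator emulates the data regimes a monotreme-style sex-chromosome
study produces, at a scaled-down genome size:

* male/female read-depth tracks over autosome, X-differentiated (X-Div),
  Y-differentiated (Y-Div) and pseudoautosomal (PAR) sequence — male X-Div
  and Y-Div are hemizygous (copy number 1), female Y-Div is absent except
  for a small contamination floor;
* Hi-C interaction records with intra-chromosomal enrichment, so unplaced
  scaffolds can be re-anchored by rank tests;
* an "old" assembly with planted N-run gaps whose closure status in the
  main ("new") assembly is known;
* planted palindromes, tandem arrays and assembly-collapsed amplicons;
* X/Y alignment segments with planted per-stratum Jukes–Cantor divergence;
* a tissue expression matrix with planted testis-specific genes.

Everything is deterministic under ``ScenarioConfig.seed``: each stage draws
from its own ``numpy`` ``SeedSequence`` child, so outputs are byte-identical
across runs and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, bin_genome
from .io import (
    AlignmentSegment,
    InteractionSet,
    SequenceRecord,
    write_bed,
    write_bedgraph,
    write_expression,
    write_fasta,
    write_interactions,
    write_segments,
)
from .tracks import WindowTrack

__all__ = [
    "PalindromePlan",
    "ArrayPlan",
    "CollapsePlan",
    "GapPlan",
    "ExpressionPlan",
    "ScenarioConfig",
    "SyntheticScenario",
    "GapTruth",
    "simulate_genome",
    "simulate_depth",
    "simulate_hic",
    "simulate_assembly_pair",
    "write_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip("ACGTN", "TGCAN"))


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Plans


@dataclass(frozen=True)
class PalindromePlan:
    scaffold: str
    start: int
    arm: int
    spacer: int
    identity: float
    repeat_decoy: bool = False  # decoy: covered by repeat annotation, must be rejected


@dataclass(frozen=True)
class ArrayPlan:
    scaffold: str
    start: int
    unit: int
    n_units: int
    identity: float  # target pairwise identity between copies


@dataclass(frozen=True)
class CollapsePlan:
    scaffold: str
    start: int
    length: int
    copies: int  # true copy number collapsed into one assembled copy


@dataclass(frozen=True)
class GapPlan:
    size: int
    outcome: str  # closed | open | trans | excluded_size | excluded_end


@dataclass(frozen=True)
class ExpressionPlan:
    n_genes: int = 60
    tissues: tuple[str, ...] = ("brain", "cerebellum", "heart", "kidney", "liver", "testis")
    testis_specific_fraction: float = 0.2
    replicates: int = 2


def _default_palindromes() -> tuple[PalindromePlan, ...]:
    return (
        PalindromePlan("scaffold_x", 5_000, 10_000, 2_000, 0.985),
        PalindromePlan("scaffold_x", 30_000, 8_000, 1_000, 0.985, repeat_decoy=True),
    )


def _default_gaps() -> tuple[GapPlan, ...]:
    plan = [GapPlan(50 * (i + 1), "closed") for i in range(10)]
    plan += [GapPlan(120 + 40 * i, "open") for i in range(5)]
    plan += [GapPlan(150 + 100 * i, "trans") for i in range(5)]
    plan += [GapPlan(4, "excluded_size"), GapPlan(300, "excluded_end")]
    return tuple(plan)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario (defaults are the
    standard conditions every recovery test runs under)."""

    seed: int = 0
    n_autosomes: int = 4
    autosome_length: int = 200_000
    par_length: int = 60_000
    stratum_length: int = 60_000
    strata_divergences: tuple[float, ...] = (0.30, 0.10, 0.03)
    y_extra_length: int = 60_000
    unplaced_par_length: int = 60_000
    unplaced_x_length: int = 50_000
    unplaced_auto_length: int = 60_000
    depth_mean: float = 30.0
    depth_dispersion: float = 150.0  # NB size parameter for 5-kb window totals
    depth_window: int = 5_000
    noise_floor: float = 0.02  # female depth floor on Y-Div, x depth_mean
    gc_base: float = 0.42
    gc_amplitude: float = 0.12
    gc_period: int = 50_000
    gc_bias_slope: float = 1.2  # depth multiplier 1 - slope*(gc - gc_base)
    hic_resolution: int = 10_000
    hic_decay_exponent: float = 1.0
    trans_ratio: float = 0.10
    hic_enrichment: float = 3.0  # unplaced-vs-truth-chromosome over trans baseline
    hic_noise_sigma: float = 0.4
    palindrome_plan: tuple[PalindromePlan, ...] = field(default_factory=_default_palindromes)
    array_plan: tuple[ArrayPlan, ...] = field(
        default_factory=lambda: (ArrayPlan("chrY1", 243_000, 5_000, 6, 0.995),)
    )
    collapse_plan: tuple[CollapsePlan, ...] = field(
        default_factory=lambda: (CollapsePlan("chrY1", 275_000, 20_000, 6),)
    )
    gap_plan: tuple[GapPlan, ...] = field(default_factory=_default_gaps)
    expression_plan: ExpressionPlan = field(default_factory=ExpressionPlan)

    def __post_init__(self) -> None:
        if self.n_autosomes < 1:
            raise ValueError("need at least one autosome")
        for d in self.strata_divergences:
            if not (0.0 <= d < 0.75):
                raise ValueError(f"stratum divergence {d} outside [0, 0.75)")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class GapTruth:
    scaffold: str
    interval: GenomicInterval
    size: int
    outcome: str  # closed | open | trans | excluded


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    genome: dict[str, str]
    chrom_names: list[str]      # anchored chromosomes
    unplaced_names: list[str]
    labels: dict[str, list[tuple[GenomicInterval, str]]]
    truth_scaffold_labels: dict[str, str]
    truth_pars: list[GenomicInterval]
    truth_palindromes: list[tuple[GenomicInterval, GenomicInterval]]
    truth_decoy_palindromes: list[tuple[GenomicInterval, GenomicInterval]]
    truth_arrays: list[GenomicInterval]
    truth_collapsed: list[tuple[GenomicInterval, int]]
    truth_strata: list[tuple[GenomicInterval, GenomicInterval, float]]
    repeats: list[GenomicInterval]
    genes: list[tuple[str, GenomicInterval]]
    scaffold_truth_chroms: dict[str, tuple[str, ...]]

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def sequence_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(n, s) for n, s in self.genome.items()]

    def sex_regions(self) -> list[GenomicInterval]:
        """Non-PAR X/Y-differentiated intervals."""
        out = []
        for scaf, parts in self.labels.items():
            for iv, lab in parts:
                if lab in ("X_div", "Y_div"):
                    out.append(iv)
        return out

    def autosome_regions(self) -> list[GenomicInterval]:
        out = []
        for scaf, parts in self.labels.items():
            for iv, lab in parts:
                if lab == "autosome":
                    out.append(iv)
        return out

    def stratum_alignment(self, i: int) -> tuple[str, str]:
        """Gapless X/Y sequence pair for stratum *i* (oldest first)."""
        x_iv, y_iv, _ = self.truth_strata[i]
        return (
            self.genome[x_iv.chrom][x_iv.start:x_iv.end],
            self.genome[y_iv.chrom][y_iv.start:y_iv.end],
        )


# ---------------------------------------------------------------------------
# Sequence helpers


def _random_seq_array(rng: np.random.Generator, length: int, cfg: ScenarioConfig) -> np.ndarray:
    """Random sequence (uint8 ASCII) with sinusoidally varying GC content."""
    pos = np.arange(length)
    p_gc = cfg.gc_base + cfg.gc_amplitude * np.sin(2 * np.pi * pos / cfg.gc_period)
    p_gc = np.clip(p_gc, 0.05, 0.95)
    is_gc = rng.random(length) < p_gc
    pick = rng.integers(0, 2, length)
    out = np.where(is_gc, np.where(pick == 0, ord("G"), ord("C")),
                   np.where(pick == 0, ord("A"), ord("T"))).astype(np.uint8)
    return out


def _jc_mutate(arr: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute sites so expected mismatch fraction is (3/4)(1-e^(-4d/3))."""
    if d <= 0:
        return arr.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    return _substitute(arr, p, rng)


def _substitute(arr: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    hit = np.flatnonzero(rng.random(len(arr)) < p)
    if len(hit):
        # pick one of the three other bases uniformly
        cur = out[hit]
        idx = np.searchsorted(_BASES, cur)  # _BASES sorted ascii: A C G T
        shift = rng.integers(1, 4, len(hit))
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _revcomp_array(arr: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        table[a] = b
    return table[arr[::-1]]


def _identity(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    matches = int(np.count_nonzero(a == b))
    return matches / len(a), matches


# ---------------------------------------------------------------------------
# Genome construction


def simulate_genome(config: ScenarioConfig) -> SyntheticScenario:
    """Build the genome and every truth table (sequence-level features only;
    depth/Hi-C/assembly/expression are emitted by their own stages)."""
    cfg = config
    rng = cfg.rng(0)
    seqs: dict[str, np.ndarray] = {}
    labels: dict[str, list[tuple[GenomicInterval, str]]] = {}
    truth_labels: dict[str, str] = {}
    truth_chroms: dict[str, tuple[str, ...]] = {}

    autosomes = [f"chrA{i + 1}" for i in range(cfg.n_autosomes)]
    for name in autosomes:
        seqs[name] = _random_seq_array(rng, cfg.autosome_length, cfg)
        labels[name] = [(GenomicInterval(name, 0, cfg.autosome_length), "autosome")]
        truth_labels[name] = "autosome"

    # X1 = PAR + X-Div (ancestral state); Y1 = same PAR + mutated Y-Div + Y-extra
    n_strata = len(cfg.strata_divergences)
    xdiv_len = n_strata * cfg.stratum_length
    par = _random_seq_array(rng, cfg.par_length, cfg)
    ancestor = _random_seq_array(rng, xdiv_len, cfg)
    ydiv = np.empty_like(ancestor)
    truth_strata: list[tuple[GenomicInterval, GenomicInterval, float]] = []
    for i, d in enumerate(cfg.strata_divergences):
        a, b = i * cfg.stratum_length, (i + 1) * cfg.stratum_length
        ydiv[a:b] = _jc_mutate(ancestor[a:b], d, rng)
        truth_strata.append(
            (
                GenomicInterval("chrX1", cfg.par_length + a, cfg.par_length + b),
                GenomicInterval("chrY1", cfg.par_length + a, cfg.par_length + b),
                d,
            )
        )
    y_extra = _random_seq_array(rng, cfg.y_extra_length, cfg)
    x1 = np.concatenate([par, ancestor])
    y1 = np.concatenate([par, ydiv, y_extra])
    seqs["chrX1"], seqs["chrY1"] = x1, y1
    labels["chrX1"] = [
        (GenomicInterval("chrX1", 0, cfg.par_length), "PAR"),
        (GenomicInterval("chrX1", cfg.par_length, len(x1)), "X_div"),
    ]
    labels["chrY1"] = [
        (GenomicInterval("chrY1", 0, cfg.par_length), "PAR"),
        (GenomicInterval("chrY1", cfg.par_length, len(y1)), "Y_div"),
    ]
    truth_labels["chrX1"] = "X_div"
    truth_labels["chrY1"] = "Y_div"

    unplaced: list[str] = []
    truth_pars = [
        GenomicInterval("chrX1", 0, cfg.par_length),
        GenomicInterval("chrY1", 0, cfg.par_length),
    ]
    if cfg.unplaced_par_length:
        seqs["scaffold_par"] = _random_seq_array(rng, cfg.unplaced_par_length, cfg)
        labels["scaffold_par"] = [
            (GenomicInterval("scaffold_par", 0, cfg.unplaced_par_length), "PAR")
        ]
        truth_labels["scaffold_par"] = "PAR"
        truth_chroms["scaffold_par"] = ("chrX1", "chrY1")
        truth_pars.append(GenomicInterval("scaffold_par", 0, cfg.unplaced_par_length))
        unplaced.append("scaffold_par")
    if cfg.unplaced_x_length:
        seqs["scaffold_x"] = _random_seq_array(rng, cfg.unplaced_x_length, cfg)
        labels["scaffold_x"] = [
            (GenomicInterval("scaffold_x", 0, cfg.unplaced_x_length), "X_div")
        ]
        truth_labels["scaffold_x"] = "X_div"
        truth_chroms["scaffold_x"] = ("chrX1",)
        unplaced.append("scaffold_x")
    if cfg.unplaced_auto_length:
        seqs["scaffold_a"] = _random_seq_array(rng, cfg.unplaced_auto_length, cfg)
        labels["scaffold_a"] = [
            (GenomicInterval("scaffold_a", 0, cfg.unplaced_auto_length), "autosome")
        ]
        truth_labels["scaffold_a"] = "autosome"
        truth_chroms["scaffold_a"] = ("chrA1",)
        unplaced.append("scaffold_a")

    # plant palindromes (inverted duplications)
    truth_pal: list[tuple[GenomicInterval, GenomicInterval]] = []
    truth_decoy: list[tuple[GenomicInterval, GenomicInterval]] = []
    repeats: list[GenomicInterval] = []
    for plan in cfg.palindrome_plan:
        seq = seqs[plan.scaffold]
        end = plan.start + 2 * plan.arm + plan.spacer
        if end > len(seq):
            raise ValueError(f"palindrome plan exceeds {plan.scaffold} length")
        arm1 = seq[plan.start:plan.start + plan.arm]
        arm2 = _substitute(_revcomp_array(arm1), 1.0 - plan.identity, rng)
        seq[plan.start + plan.arm + plan.spacer:end] = arm2
        ivs = (
            GenomicInterval(plan.scaffold, plan.start, plan.start + plan.arm),
            GenomicInterval(plan.scaffold, plan.start + plan.arm + plan.spacer, end),
        )
        if plan.repeat_decoy:
            truth_decoy.append(ivs)
            span = end - plan.start
            pad = int(span * 0.05)  # cover ~90% of the span with "repeat"
            repeats.append(GenomicInterval(plan.scaffold, plan.start + pad, end - pad))
        else:
            truth_pal.append(ivs)

    # plant tandem arrays
    truth_arrays: list[GenomicInterval] = []
    for plan in cfg.array_plan:
        seq = seqs[plan.scaffold]
        total = plan.unit * plan.n_units
        if plan.start + total > len(seq):
            raise ValueError(f"array plan exceeds {plan.scaffold} length")
        master = _random_seq_array(rng, plan.unit, cfg)
        per_copy_rate = (1.0 - plan.identity) / 2.0
        for i in range(plan.n_units):
            a = plan.start + i * plan.unit
            seq[a:a + plan.unit] = _substitute(master, per_copy_rate, rng)
        truth_arrays.append(GenomicInterval(plan.scaffold, plan.start, plan.start + total))

    # collapsed amplicons only alter depth, not sequence
    truth_collapsed = [
        (GenomicInterval(p.scaffold, p.start, p.start + p.length), p.copies)
        for p in cfg.collapse_plan
    ]
    for iv, _ in truth_collapsed:
        if iv.end > len(seqs[iv.chrom]):
            raise ValueError(f"collapse plan exceeds {iv.chrom} length")

    # a couple of ordinary interspersed repeats on autosomes (background)
    repeats.append(GenomicInterval("chrA1", 120_000 % cfg.autosome_length or 1_000,
                                   (120_000 % cfg.autosome_length or 1_000) + 2_000))
    repeats.append(GenomicInterval("chrA2", 50_000 % cfg.autosome_length or 1_000,
                                   (50_000 % cfg.autosome_length or 1_000) + 3_000))

    # gene models: amplicon genes inside planted features, controls elsewhere
    genes: list[tuple[str, GenomicInterval]] = []
    if truth_pal:
        p0 = truth_pal[0][0]
        genes.append(("AmpX1", GenomicInterval(p0.chrom, p0.start + 1_000, p0.start + 6_000)))
    if truth_arrays:
        a0 = truth_arrays[0]
        genes.append(("AmpY2", GenomicInterval(a0.chrom, a0.start + 3_000, a0.start + 8_000)))
        genes.append(("OR5A1", GenomicInterval(a0.chrom, a0.start + 12_000, a0.start + 16_000)))
    if truth_collapsed:
        c0, _ = truth_collapsed[0]
        genes.append(("AmpY1", GenomicInterval(c0.chrom, c0.start + 2_000, c0.start + 8_000)))
        # 19 kb of a 24-kb gene inside the collapsed region: 79% overlap, below cut-off
        genes.append(("EdgeGene", GenomicInterval(c0.chrom, c0.end - 19_000, c0.end + 5_000)))
    genes.append(("HK1", GenomicInterval("chrA1", 20_000, 26_000)))
    genes.append(("HK2", GenomicInterval("chrA2", 80_000, 84_000)))

    genome = {name: arr.tobytes().decode("ascii") for name, arr in seqs.items()}
    return SyntheticScenario(
        config=cfg,
        genome=genome,
        chrom_names=autosomes + ["chrX1", "chrY1"],
        unplaced_names=unplaced,
        labels=labels,
        truth_scaffold_labels=truth_labels,
        truth_pars=truth_pars,
        truth_palindromes=truth_pal,
        truth_decoy_palindromes=truth_decoy,
        truth_arrays=truth_arrays,
        truth_collapsed=truth_collapsed,
        truth_strata=truth_strata,
        repeats=repeats,
        genes=genes,
        scaffold_truth_chroms=truth_chroms,
    )


# ---------------------------------------------------------------------------
# Depth


_COPY_NUMBER = {
    # label -> (male, female) copies
    "autosome": (2.0, 2.0),
    "PAR": (2.0, 2.0),
    "X_div": (1.0, 2.0),
    "Y_div": (1.0, 0.0),
}


def _gc_per_window(seq: str, windows: list[GenomicInterval]) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(gc)])
    return np.array([(cs[w.end] - cs[w.start]) / len(w) for w in windows])


def gc_track(scenario: SyntheticScenario, window: int | None = None) -> WindowTrack:
    """Per-window GC fraction computed from the emitted sequence."""
    cfg = scenario.config
    w = window or cfg.depth_window
    windows = bin_genome(scenario.chrom_sizes(), w)
    vals = []
    for chrom in scenario.genome:
        sub = [x for x in windows if x.chrom == chrom]
        vals.append(_gc_per_window(scenario.genome[chrom], sub))
    return WindowTrack(windows, np.concatenate(vals))


def simulate_depth(scenario: SyntheticScenario, sex: str,
                   window: int | None = None) -> WindowTrack:
    """Per-window mean depth for one sex (negative-binomial window totals).

    The window mean is ``depth_mean * copy_number / 2`` scaled by a linear
    GC bias (the signal the GC-correction stage must remove), floored at
    ``noise_floor * depth_mean`` so female Y windows stay positive.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    cfg = scenario.config
    w = window or cfg.depth_window
    rng = cfg.rng(10 if sex == "male" else 11)
    windows = bin_genome(scenario.chrom_sizes(), w)
    sexi = 0 if sex == "male" else 1

    # per-base copy number per scaffold, then window means
    values = np.empty(len(windows))
    pos = 0
    for chrom, seq in scenario.genome.items():
        sub = [x for x in windows if x.chrom == chrom]
        cn = np.zeros(len(seq))
        for iv, lab in scenario.labels[chrom]:
            cn[iv.start:iv.end] = _COPY_NUMBER[lab][sexi]
        for iv, copies in scenario.truth_collapsed:
            if iv.chrom == chrom:
                cn[iv.start:iv.end] *= copies
        cs = np.concatenate([[0.0], np.cumsum(cn)])
        gc = _gc_per_window(seq, sub)
        bias = np.clip(1.0 - cfg.gc_bias_slope * (gc - cfg.gc_base), 0.2, None)
        for j, x in enumerate(sub):
            mean_cn = (cs[x.end] - cs[x.start]) / len(x)
            mean_depth = max(cfg.depth_mean * mean_cn / 2.0 * bias[j],
                             cfg.noise_floor * cfg.depth_mean)
            total_mean = mean_depth * len(x)
            k = cfg.depth_dispersion
            total = rng.negative_binomial(k, k / (k + total_mean))
            values[pos + j] = total / len(x)
        pos += len(sub)
    return WindowTrack(windows, values)


# ---------------------------------------------------------------------------
# Hi-C


def simulate_hic(scenario: SyntheticScenario,
                 resolution: int | None = None) -> InteractionSet:
    """All-pairs bin interactions: power-law intra decay, flat trans
    baseline, planted enrichment between unplaced scaffolds and their truth
    chromosome(s), multiplicative lognormal noise."""
    cfg = scenario.config
    res = resolution or cfg.hic_resolution
    rng = cfg.rng(20)
    bins: list[tuple[str, int]] = []
    for name, seq in scenario.genome.items():
        for start in range(0, max(len(seq), 1), res):
            bins.append((name, start))

    def truth_set(name: str) -> tuple[str, ...]:
        if name in scenario.chrom_names:
            return (name,)
        return scenario.scaffold_truth_chroms.get(name, ())

    rows_a, starts_a, rows_b, starts_b, means = [], [], [], [], []
    n = len(bins)
    for i in range(n):
        ca, sa = bins[i]
        ta = truth_set(ca)
        for j in range(i + 1, n):
            cb, sb = bins[j]
            if ca == cb:
                d = abs(sa - sb)
                mean = (1.0 + d / res) ** (-cfg.hic_decay_exponent)
            elif set(ta) & set(truth_set(cb)):
                mean = cfg.hic_enrichment * cfg.trans_ratio
            else:
                mean = cfg.trans_ratio
            rows_a.append(ca); starts_a.append(sa)
            rows_b.append(cb); starts_b.append(sb)
            means.append(mean)
    noise = rng.lognormal(0.0, cfg.hic_noise_sigma, len(means))
    df = pd.DataFrame(
        {
            "chrom_a": rows_a,
            "start_a": starts_a,
            "chrom_b": rows_b,
            "start_b": starts_b,
            "strength": np.asarray(means) * noise,
        }
    )
    return InteractionSet(df, res)


# ---------------------------------------------------------------------------
# Assembly pair with planted gaps


def simulate_assembly_pair(
    scenario: SyntheticScenario,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[GapTruth]]:
    """Old assembly with planted N-run gaps, the new assembly, and truth.

    Each planned gap becomes one old-assembly scaffold built from flank
    sequence copied out of the new assembly: ``closed`` gaps have both
    flanks contiguous on one new scaffold; ``trans`` flanks come from two
    scaffolds; ``open`` gaps get a downstream flank absent from the new
    assembly; exclusions are realized by size (<5 bp) or by placing the gap
    <200 bp from the old scaffold end.
    """
    cfg = scenario.config
    rng = cfg.rng(30)
    new = scenario.sequence_records()
    donors = [n for n in scenario.chrom_names if n.startswith("chrA")]
    cursors = {d: 10_000 for d in donors}

    def take(donor: str, length: int) -> str:
        start = cursors[donor]
        cursors[donor] += length + 900
        seq = scenario.genome[donor][start:start + length]
        if len(seq) < length:
            raise ValueError("autosomes too short for the gap plan")
        return seq

    flank = 600  # donor context per side; mapper uses the inner 500 bp
    old: list[SequenceRecord] = []
    truth: list[GapTruth] = []
    for idx, plan in enumerate(scenario.config.gap_plan):
        name = f"gap_scaffold_{idx:03d}"
        if plan.outcome == "closed":
            donor = donors[0]
            start = cursors[donor]
            cursors[donor] += 2 * flank + 900
            up = scenario.genome[donor][start:start + flank]
            down = scenario.genome[donor][start + flank:start + 2 * flank]
            seq = up + "N" * plan.size + down
            gap_iv = GenomicInterval(name, flank, flank + plan.size)
            label = "closed"
        elif plan.outcome == "trans":
            up = take(donors[0], flank)
            down = take(donors[1 % len(donors)], flank)
            seq = up + "N" * plan.size + down
            gap_iv = GenomicInterval(name, flank, flank + plan.size)
            label = "trans"
        elif plan.outcome == "open":
            up = take(donors[2 % len(donors)], flank)
            down = _random_seq_array(rng, flank, cfg).tobytes().decode("ascii")
            seq = up + "N" * plan.size + down
            gap_iv = GenomicInterval(name, flank, flank + plan.size)
            label = "open"
        elif plan.outcome == "excluded_size":
            donor = donors[3 % len(donors)]
            start = cursors[donor]
            cursors[donor] += 2 * flank + 900
            up = scenario.genome[donor][start:start + flank]
            down = scenario.genome[donor][start + flank:start + 2 * flank]
            seq = up + "N" * plan.size + down
            gap_iv = GenomicInterval(name, flank, flank + plan.size)
            label = "excluded"
        elif plan.outcome == "excluded_end":
            up = take(donors[3 % len(donors)], 150)
            down = take(donors[3 % len(donors)], flank)
            seq = up + "N" * plan.size + down
            gap_iv = GenomicInterval(name, 150, 150 + plan.size)
            label = "excluded"
        else:
            raise ValueError(f"unknown gap outcome {plan.outcome!r}")
        old.append(SequenceRecord(name, seq))
        truth.append(GapTruth(name, gap_iv, plan.size, label))
    return old, new, truth


# ---------------------------------------------------------------------------
# Alignment-segment emission


def self_segments(scenario: SyntheticScenario) -> list[AlignmentSegment]:
    """Self-alignment hit table over the sex-linked sequences: inverted
    palindrome-arm hits plus forward array unit-vs-unit hits, with measured
    identities (the trivial self diagonal is never emitted)."""
    segs: list[AlignmentSegment] = []
    for arm1, arm2 in scenario.truth_palindromes + scenario.truth_decoy_palindromes:
        a = np.frombuffer(scenario.genome[arm1.chrom][arm1.start:arm1.end].encode(), np.uint8)
        b = np.frombuffer(scenario.genome[arm2.chrom][arm2.start:arm2.end].encode(), np.uint8)
        ident, matches = _identity(a, _revcomp_array(b))
        segs.append(AlignmentSegment(arm1, arm2, "-", ident, len(arm1), matches))
    for plan in scenario.config.array_plan:
        units = [
            GenomicInterval(plan.scaffold, plan.start + i * plan.unit,
                            plan.start + (i + 1) * plan.unit)
            for i in range(plan.n_units)
        ]
        arrs = [
            np.frombuffer(
                scenario.genome[u.chrom][u.start:u.end].encode(), np.uint8
            )
            for u in units
        ]
        for i in range(len(units)):
            for j in range(len(units)):
                if i == j:
                    continue
                ident, matches = _identity(arrs[i], arrs[j])
                segs.append(AlignmentSegment(units[i], units[j], "+", ident,
                                             plan.unit, matches))
    return segs


def xy_segments(scenario: SyntheticScenario, chunk: int = 4_000) -> list[AlignmentSegment]:
    """X-vs-Y alignment blocks per stratum (query = X, target = Y), with
    measured identity and match counts per chunk."""
    segs: list[AlignmentSegment] = []
    for x_iv, y_iv, _ in scenario.truth_strata:
        xs = np.frombuffer(
            scenario.genome[x_iv.chrom][x_iv.start:x_iv.end].encode(), np.uint8
        )
        ys = np.frombuffer(
            scenario.genome[y_iv.chrom][y_iv.start:y_iv.end].encode(), np.uint8
        )
        for a in range(0, len(xs), chunk):
            b = min(a + chunk, len(xs))
            ident, matches = _identity(xs[a:b], ys[a:b])
            segs.append(
                AlignmentSegment(
                    GenomicInterval(x_iv.chrom, x_iv.start + a, x_iv.start + b),
                    GenomicInterval(y_iv.chrom, y_iv.start + a, y_iv.start + b),
                    "+", ident, b - a, matches,
                )
            )
    return segs


def y_vs_other_segments(
    scenario: SyntheticScenario, xy: list[AlignmentSegment] | None = None
) -> tuple[list[AlignmentSegment], list[int]]:
    """Competing Y-vs-autosome/PAR hits plus the indices of X/Y segments
    they should knock out (first segment of the oldest stratum gets a
    strictly better autosomal hit; the second gets an equal-identity hit
    that must be kept)."""
    if xy is None:
        xy = xy_segments(scenario)
    competitors: list[AlignmentSegment] = []
    drop: list[int] = []
    if xy:
        target = xy[0]
        competitors.append(
            AlignmentSegment(
                q_interval=target.t_interval,
                t_interval=GenomicInterval("chrA1", 5_000, 5_000 + target.aligned_length + 500),
                strand="+",
                identity=min(1.0, target.identity + 0.05),
                aligned_length=target.aligned_length + 500,
            )
        )
        drop.append(0)
    if len(xy) > 1:
        keeper = xy[1]
        competitors.append(
            AlignmentSegment(
                q_interval=keeper.t_interval,
                t_interval=GenomicInterval("chrA2", 9_000, 9_000 + keeper.aligned_length),
                strand="+",
                identity=keeper.identity,  # tie: filter must keep the X/Y segment
                aligned_length=keeper.aligned_length + 800,
            )
        )
    return competitors, drop


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(scenario: SyntheticScenario) -> tuple[pd.DataFrame, set[str]]:
    """TPM-like matrix (genes x tissue.replicate) with planted
    testis-specific genes; returns the matrix and the truth set."""
    cfg = scenario.config
    plan = cfg.expression_plan
    rng = cfg.rng(40)
    amp_names = [n for n, _ in scenario.genes if n.startswith("Amp")]
    names = list(dict.fromkeys(amp_names))
    names += [f"gene_{i:03d}" for i in range(plan.n_genes - len(names))]
    n_specific = max(len(amp_names), round(plan.testis_specific_fraction * plan.n_genes))
    specific = set(names[:n_specific])

    cols = [f"{t}.rep{r + 1}" for t in plan.tissues for r in range(plan.replicates)]
    data = np.empty((len(names), len(cols)))
    for gi, g in enumerate(names):
        if g in specific:
            for ci, col in enumerate(cols):
                tissue = col.split(".")[0]
                if tissue == "testis":
                    data[gi, ci] = rng.lognormal(np.log(100.0), 0.3)
                else:
                    data[gi, ci] = rng.uniform(0.0, 2.0)
        else:
            base = rng.lognormal(np.log(30.0), 0.5)
            per_tissue = {t: base * rng.lognormal(0.0, 0.3) for t in plan.tissues}
            for ci, col in enumerate(cols):
                tissue = col.split(".")[0]
                data[gi, ci] = per_tissue[tissue] * rng.lognormal(0.0, 0.1)
    df = pd.DataFrame(data, index=pd.Index(names, name="gene"), columns=cols)
    return df, specific


# ---------------------------------------------------------------------------
# Scenario writer


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> None:
    """Emit every standard-format file plus plain-TSV truth tables."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", scenario.sequence_records())
    write_bedgraph(out / "depth_male.bedgraph", simulate_depth(scenario, "male"))
    write_bedgraph(out / "depth_female.bedgraph", simulate_depth(scenario, "female"))
    write_bedgraph(out / "gc.bedgraph", gc_track(scenario))
    write_interactions(out / "hic.tsv", simulate_hic(scenario))
    write_segments(out / "self_aln.tsv", self_segments(scenario))
    xy = xy_segments(scenario)
    write_segments(out / "xy_aln.tsv", xy)
    competitors, _ = y_vs_other_segments(scenario, xy)
    write_segments(out / "y_vs_other.tsv", competitors)
    write_bed(out / "repeats.bed", scenario.repeats)
    write_bed(out / "genes.bed", [iv for _, iv in scenario.genes],
              names=[n for n, _ in scenario.genes])
    write_bed(out / "sex_regions.bed", scenario.sex_regions())
    write_bed(out / "autosome_regions.bed", scenario.autosome_regions())
    old, _, gap_truth = simulate_assembly_pair(scenario)
    write_fasta(out / "old_assembly.fa", old)
    expr, specific = simulate_expression(scenario)
    write_expression(out / "expression.tsv", expr)

    with open(out / "truth" / "scaffold_labels.tsv", "w") as fh:
        for scaf, lab in scenario.truth_scaffold_labels.items():
            fh.write(f"{scaf}\t{lab}\n")
    write_bed(out / "truth" / "pars.bed", scenario.truth_pars)
    with open(out / "truth" / "gaps.tsv", "w") as fh:
        for g in gap_truth:
            fh.write(f"{g.scaffold}\t{g.interval.start}\t{g.interval.end}\t{g.size}\t{g.outcome}\n")
    with open(out / "truth" / "strata.tsv", "w") as fh:
        for x_iv, y_iv, d in scenario.truth_strata:
            fh.write(
                f"{x_iv.chrom}\t{x_iv.start}\t{x_iv.end}\t"
                f"{y_iv.chrom}\t{y_iv.start}\t{y_iv.end}\t{d}\n"
            )
    pal_rows = [iv for pair in scenario.truth_palindromes for iv in pair]
    write_bed(out / "truth" / "palindrome_arms.bed", pal_rows)
    write_bed(out / "truth" / "arrays.bed", scenario.truth_arrays)
    write_bed(out / "truth" / "collapsed.bed", [iv for iv, _ in scenario.truth_collapsed])
    with open(out / "truth" / "specific_genes.tsv", "w") as fh:
        for g in sorted(specific):
            fh.write(g + "\n")
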