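"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
FASTA
    via Biopython; sequences uppercased on read, alphabet {A,C,G,T,N}.
BED3 / BED6
    0-based half-open, tab-separated.
bedGraph
    ``chrom  start  end  value`` with ``NA`` for missing values.
Alignment-segment TSV
    columns ``q_name q_start q_end t_name t_strand t_start t_end
    identity_pct aligned_len [matches]`` — mirrors a lastZ
    ``--format=general`` field list.  Both query and target coordinates are
    0-based half-open on the forward strand; an inverted alignment is
    flagged by ``t_strand = '-'`` with the target span still stored
    forward, which keeps all downstream interval algebra in one coordinate
    system.
Interaction TSV
    ``chrom_a start_a chrom_b start_b strength`` with a mandatory
    ``#resolution=<bp>`` header line.
Expression TSV
    genes x samples matrix; sample columns may be ``tissue`` or
    ``tissue.replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .intervals import GenomicInterval
from .tracks import WindowTrack

__all__ = [
    "ParseError",
    "SequenceRecord",
    "AlignmentSegment",
    "InteractionSet",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_segments",
    "write_segments",
    "read_interactions",
    "write_interactions",
    "read_expression",
    "write_expression",
]

_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input line; carries file name and 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class SequenceRecord:
    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        extra = set(self.seq) - _ALPHABET
        if extra:
            raise ValueError(
                f"sequence {self.name} contains letters outside ACGTN: {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentSegment:
    """One pairwise local alignment block between a query and a target span.

    ``strand`` is the orientation of the target relative to the query; for
    ``'-'`` the target interval is stored on the forward strand.
    """

    q_interval: GenomicInterval
    t_interval: GenomicInterval
    strand: str
    identity: float
    aligned_length: int
    matches: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if self.matches is not None and self.matches > self.aligned_length:
            raise ValueError("matches cannot exceed aligned_length")


@dataclass
class InteractionSet:
    """Hi-C interaction records at a fixed, declared bin resolution."""

    records: pd.DataFrame  # chrom_a, start_a, chrom_b, start_b, strength
    resolution: int

    def __post_init__(self) -> None:
        need = ["chrom_a", "start_a", "chrom_b", "start_b", "strength"]
        if list(self.records.columns) != need:
            raise ValueError(f"interaction records need columns {need}")
        if self.resolution < 1:
            raise ValueError("resolution must be positive")
        if (self.records["strength"] < 0).any():
            raise ValueError("interaction strengths must be >= 0")

    def scaffolds(self) -> set[str]:
        return set(self.records["chrom_a"]) | set(self.records["chrom_b"])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(path, 0, f"duplicate sequence name {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord], width: int = 80) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.name, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >= 3 BED fields, got {len(fields)}")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if len(fields) >= 6 and fields[5] not in ("+", "-", "."):
                raise ParseError(path, lineno, f"unknown strand symbol {fields[5]!r}")
            out.append(iv)
    return out


def read_bed6(path: str | Path) -> list[tuple[str, GenomicInterval, str]]:
    """BED6 reader returning (name, interval, strand) triples."""
    out: list[tuple[str, GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected 6 BED fields, got {len(fields)}")
            if fields[5] not in ("+", "-", "."):
                raise ParseError(path, lineno, f"unknown strand symbol {fields[5]!r}")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            out.append((fields[3], iv, fields[5]))
    return out


def write_bed(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
    strands: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                strand = strands[i] if strands is not None else "."
                cols += [names[i], "0", strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> WindowTrack:
    windows: list[GenomicInterval] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 bedGraph fields, got {len(fields)}")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                val = float("nan") if fields[3] == "NA" else float(fields[3])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            windows.append(iv)
            values.append(val)
    return WindowTrack(windows, np.array(values))


def write_bedgraph(path: str | Path, track: WindowTrack) -> None:
    with open(path, "w") as fh:
        for w, v in zip(track.windows, track.values):
            sval = "NA" if np.isnan(v) else format(float(v), ".6g")
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{sval}\n")


# ---------------------------------------------------------------------------
# Alignment segments

_SEG_COLS = [
    "q_name", "q_start", "q_end", "t_name", "t_strand", "t_start", "t_end",
    "identity_pct", "aligned_len",
]


def read_segments(path: str | Path) -> list[AlignmentSegment]:
    out: list[AlignmentSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (9, 10):
                raise ParseError(path, lineno, f"expected 9 or 10 fields, got {len(fields)}")
            try:
                seg = AlignmentSegment(
                    q_interval=GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    t_interval=GenomicInterval(fields[3], int(fields[5]), int(fields[6])),
                    strand=fields[4],
                    identity=float(fields[7]) / 100.0,
                    aligned_length=int(fields[8]),
                    matches=int(fields[9]) if len(fields) == 10 and fields[9] != "NA" else None,
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            out.append(seg)
    return out


def write_segments(path: str | Path, segments: Iterable[AlignmentSegment]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_SEG_COLS + ["matches"]) + "\n")
        for s in segments:
            fh.write(
                "\t".join(
                    [
                        s.q_interval.chrom, str(s.q_interval.start), str(s.q_interval.end),
                        s.t_interval.chrom, s.strand,
                        str(s.t_interval.start), str(s.t_interval.end),
                        format(s.identity * 100.0, ".4f"), str(s.aligned_length),
                        "NA" if s.matches is None else str(s.matches),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Hi-C interactions


def read_interactions(path: str | Path) -> InteractionSet:
    resolution: int | None = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#resolution="):
        resolution = int(first.split("=", 1)[1])
    if resolution is None:
        raise ParseError(path, 1, "missing '#resolution=<bp>' header line")
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom_a", "start_a", "chrom_b", "start_b", "strength"],
        dtype={"chrom_a": str, "start_a": int, "chrom_b": str, "start_b": int,
               "strength": float},
    )
    return InteractionSet(df, resolution)


def write_interactions(path: str | Path, interactions: InteractionSet) -> None:
    with open(path, "w") as fh:
        fh.write(f"#resolution={interactions.resolution}\n")
        interactions.records.to_csv(fh, sep="\t", header=False, index=False,
                                    float_format="%.6g")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    if df.shape[1] < 2:
        raise ParseError(path, 1, "expression matrix needs >= 2 sample columns")
    if (df.values < 0).any():
        raise ParseError(path, 1, "negative expression values")
    return df


def write_expression(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")
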