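"""Sequence and interval primitives shared by every analysis stage.

Coordinates follow the NCBI reporting convention everywhere in the public
API: 1-based, inclusive on both ends. BED files are converted to and from
0-based half-open form only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Topology = str  # "circular" | "linear"
Compartment = str  # "mitochondrion" | "plastid" | "nucleus" | "unknown"


class FormatError(ValueError):
    """Malformed input file (names the offending record where possible)."""


class CoordinateError(ValueError):
    """Interval or position outside the bounds of its sequence."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One nucleotide sequence with its replicon topology and compartment.

    Plant organelle genomes typically map as single circular molecules;
    nuclear chromosomes are linear. The distinction matters only for
    origin-spanning extraction and self-alignment.
    """

    id: str
    sequence: str
    topology: Topology = "linear"
    compartment: Compartment = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise FormatError(
                f"record {self.id!r}: disallowed characters {sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_percent(self) -> float:
        return gc_content(self.sequence)


def gc_content(seq: str) -> float:
    """GC percentage of a sequence region.

    N (and any ambiguity already collapsed to N on input) is excluded from
    both numerator and denominator. Raises on an all-N region, where base
    composition is undefined.
    """
    g = seq.count("G")
    c = seq.count("C")
    denom = g + c + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("undefined composition: region contains no A/C/G/T")
    return 100.0 * (g + c) / denom


def read_fasta(
    path: str | Path,
    topology: Topology = "linear",
    compartment: Compartment = "unknown",
) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords.

    Lowercase is folded to uppercase; any residue outside {A,C,G,T,N} is
    mapped to N and the per-file count is logged. Empty files, records
    without an identifier, and zero-length records raise FormatError.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has zero length")
        cleaned = []
        for ch in seq:
            if ch in _ALLOWED:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_mapped += 1
        records.append(
            GenomeRecord(
                id=rec.id,
                sequence="".join(cleaned),
                topology=topology,
                compartment=compartment,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if n_mapped:
        log.info("%s: mapped %d non-ACGTN characters to N", path, n_mapped)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass(frozen=True, order=True)
class Interval:
    """Closed interval [start, end] on a named sequence, 1-based."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"bad interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class IntervalSet:
    """Non-redundant (strand-collapsed) coverage on one sequence.

    This is the unit of every "overlaps excluded" statistic: adding an
    already-covered base never changes total_length.
    """

    seq_id: str
    intervals: list[Interval] = field(default_factory=list)

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[Interval],
        seq_id: str | None = None,
        seq_length: int | None = None,
    ) -> "IntervalSet":
        ids = {iv.seq_id for iv in intervals}
        if seq_id is None:
            if len(ids) > 1:
                raise ValueError(f"intervals span multiple sequences: {sorted(ids)}")
            seq_id = next(iter(ids)) if ids else ""
        elif ids - {seq_id}:
            raise ValueError(f"intervals not all on {seq_id!r}: {sorted(ids)}")
        if seq_length is not None:
            for iv in intervals:
                if iv.end > seq_length:
                    raise CoordinateError(
                        f"{iv.seq_id}:{iv.start}-{iv.end} beyond length {seq_length}"
                    )
        merged: list[Interval] = []
        for iv in sorted(intervals, key=lambda x: (x.start, x.end)):
            if merged and iv.start <= merged[-1].end + 1:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = Interval(seq_id, last.start, iv.end)
            else:
                merged.append(Interval(seq_id, iv.start, iv.end))
        return cls(seq_id=seq_id, intervals=merged)

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        if other.seq_id != self.seq_id and self.intervals and other.intervals:
            raise ValueError("cannot union interval sets on different sequences")
        return IntervalSet.from_intervals(
            list(self.intervals) + list(other.intervals),
            seq_id=self.seq_id or other.seq_id,
        )

    def covered_fraction(self, seq_length: int) -> float:
        return self.total_length / seq_length

    def contains(self, pos: int) -> bool:
        return any(iv.start <= pos <= iv.end for iv in self.intervals)


def merge_and_measure(intervals: Sequence[Interval], seq_length: int | None = None) -> tuple[IntervalSet, int]:
    """Union coverage of a batch of intervals plus total covered bp.

    Idempotent and order-independent; the core primitive behind every
    repeat-percentage and shared-DNA total in the package.
    """
    iset = IntervalSet.from_intervals(intervals, seq_length=seq_length)
    return iset, iset.total_length


def extract_region(record: GenomeRecord, start: int, end: int, strand: str = "+") -> str:
    """Extract [start, end] (1-based inclusive); minus strand reverse-complements.

    On circular records a start greater than the end wraps across the
    origin (e.g. start=len-1, end=2 returns 4 bases).
    """
    n = len(record.sequence)
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    if not (1 <= start <= n and 1 <= end <= n):
        raise CoordinateError(
            f"{record.id}: coordinates {start}-{end} outside 1..{n}"
        )
    if start <= end:
        seq = record.sequence[start - 1 : end]
    else:
        if record.topology != "circular":
            raise CoordinateError(
                f"{record.id}: start > end on a linear record ({start} > {end})"
            )
        seq = record.sequence[start - 1 :] + record.sequence[:end]
    return revcomp(seq) if strand == "-" else seq


def translate(seq: str, table: int = 1, to_stop: bool = False) -> str:
    """Translate a nucleotide string (frame 0) with the given codon table."""
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate(table=table, to_stop=to_stop))


# ---------------------------------------------------------------------------
# BED boundary conversion (0-based half-open on disk, 1-based in memory)

def write_bed(intervals: Iterable[Interval], path: str | Path, names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.seq_id}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: short BED line {line!r}")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append(Interval(parts[0], int(parts[1]) + 1, int(parts[2]), strand))
    return out
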