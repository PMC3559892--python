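"""Genomic file formats and shared interval conventions.

Every coordinate in this package is BED-style: 0-based, half-open
``[start, end)``.  Reads carry a mandatory strand (``+``/``-``); an
unknown strand (``.``) is rejected rather than coerced, because the
strand-specific overlap scoring downstream is undefined without it.

Supported formats:

* BED6 for aligned reads (strand in column 6),
* BED4+ for repeat annotations (column 4 = repeat name, e.g. ``HSATII``;
  an optional non-numeric column 5 is taken as the repeat class),
* plain FASTA for the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Name of the class-label column in every feature matrix DataFrame.
LABEL_COLUMN = "label"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: IUPAC nucleotide codes accepted in genome FASTA input.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")


class BedFormatError(ValueError):
    """A BED line violates the dialect expected by the pipeline."""


class FastaFormatError(ValueError):
    """A FASTA file violates basic well-formedness (duplicate header, bad symbol)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + delta, self.end + delta)


@dataclass(frozen=True, order=True)
class Read:
    """One aligned sequencing read: an interval plus a mandatory strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' end: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated repeat instance (RepeatMasker-style)."""

    interval: GenomicInterval
    rep_name: str
    rep_class: str = ""

    def __post_init__(self) -> None:
        if not self.rep_name:
            raise ValueError("rep_name must be non-empty")


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> list[Read]:
    """Parse a BED6 file of aligned reads.

    Requires at least six whitespace-separated columns per data line with the
    strand in column 6.  Raises :class:`BedFormatError` naming the offending
    line on malformed input.  Input order is preserved.
    """
    reads: list[Read] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 6:
            raise BedFormatError(
                f"{path}: line {lineno}: expected >= 6 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedFormatError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from exc
        strand = fields[5]
        try:
            reads.append(Read(fields[0], start, end, strand))
        except ValueError as exc:
            raise BedFormatError(f"{path}: line {lineno}: {exc}") from exc
    return reads


def write_bed(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as BED6 (name = running index, score = 0)."""
    with open(path, "w") as handle:
        for i, read in enumerate(reads):
            handle.write(
                f"{read.chrom}\t{read.start}\t{read.end}\tread{i}\t0\t{read.strand}\n"
            )


def read_repeat_bed(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a BED4+ repeat-annotation file (column 4 = repName).

    An optional fifth column, when present and non-numeric, is taken as the
    repeat class (e.g. ``Satellite``).
    """
    annotations: list[RepeatAnnotation] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 4:
            raise BedFormatError(
                f"{path}: line {lineno}: expected >= 4 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedFormatError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from exc
        rep_class = ""
        if len(fields) >= 5 and not fields[4].lstrip("-").isdigit():
            rep_class = fields[4]
        try:
            annotations.append(
                RepeatAnnotation(GenomicInterval(fields[0], start, end), fields[3], rep_class)
            )
        except ValueError as exc:
            raise BedFormatError(f"{path}: line {lineno}: {exc}") from exc
    return annotations


def write_repeat_bed(annotations: Iterable[RepeatAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        for ann in annotations:
            iv = ann.interval
            cls = ann.rep_class or "."
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ann.rep_name}\t{cls}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``.

    Duplicate headers and non-IUPAC characters are format errors.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FastaFormatError(f"{path}: duplicate header {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FastaFormatError(
                f"{path}: record {record.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        genome[record.id] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def extract_sequence(
    genome: Mapping[str, str], interval: GenomicInterval, strand: str = "+"
) -> str:
    """Extract the sequence of ``interval``; reverse complement when ``strand == '-'``."""
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) outside {interval.chrom} "
            f"of length {len(chrom_seq)}"
        )
    sub = chrom_seq[interval.start : interval.end]
    return reverse_complement(sub) if strand == "-" else sub


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled feature matrix as TSV (row id index, ``label`` column first)."""
    matrix.to_csv(path, sep="\t", index_label="id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
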