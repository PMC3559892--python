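"""Synthetic ChIP-Seq dataset generator.

Builds a toy genome with planted pericentromeric-style satellite II / III
arrays, plants stable nucleosomes of two mutually exclusive outcome marks
(positive-class nucleosomes inside satellite arrays, negative-class
nucleosomes in unique background sequence), and simulates strand-structured
read pileups with PCR duplicates, uniform background reads and per-sample
depth multipliers.  Every downstream stage of the pipeline is testable
against the planted truth without any external download.

Satellite consensus grammars
----------------------------
* satellite II unit: two copies of ``ATTCCATTCG`` followed by 1-2 copies of
  ``ATG`` (emitted uppercase; lower case in published consensus tables
  encodes conservation, not sequence),
* satellite III unit: 7-13 copies of ``ATTCC`` followed by one
  ``ATTCGGGTTG``.

Arrays are concatenations of independently drawn units, annotated with the
RepeatMasker-style names ``HSATII`` (satellite II) and ``(CATTC)n`` /
``(GAATG)n`` (satellite III).

Read model
----------
Reads are 25 bp.  For a planted nucleosome, ``~Poisson(reads_per_nuc / 2)``
plus-strand reads have 5' ends jittered around one bp upstream of the
nucleosome 5' edge, and the mirrored count of minus-strand reads have 5'
ends jittered around the 3' edge — the geometry assumed by 3'-extension to
150 bp in the peak caller.  Both classes are planted with the same
read-count distribution so that classes differ only in sequence context and
feature co-localization, never in coverage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    Read,
    RepeatAnnotation,
    write_bed,
    write_fasta,
    write_repeat_bed,
)

SAT2_CORE = "ATTCCATTCG"
SAT2_SPACER = "ATG"
SAT3_CORE = "ATTCC"
SAT3_SPACER = "ATTCGGGTTG"

#: 19 histone methylations + 18 histone acetylations used as feature channels.
METHYLATION_CHANNELS = [
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9me1", "H3K9me2", "H3K9me3",
    "H3K27me1", "H3K27me2", "H3K27me3", "H3K36me1", "H3K36me3",
    "H3K79me1", "H3K79me2", "H3K79me3", "H4K20me1", "H4K20me3",
    "H3R2me1", "H3R2me2a", "H2BK5me1",
]
ACETYLATION_CHANNELS = [
    "H2AK5ac", "H2AK9ac", "H2BK5ac", "H2BK12ac", "H2BK20ac", "H2BK120ac",
    "H3K4ac", "H3K9ac", "H3K14ac", "H3K18ac", "H3K23ac", "H3K27ac",
    "H3K36ac", "H4K5ac", "H4K8ac", "H4K12ac", "H4K16ac", "H4K91ac",
]
DEFAULT_FEATURE_CHANNELS = METHYLATION_CHANNELS + ACETYLATION_CHANNELS

NUCLEOSOME_WIDTH = 147


class SyntheticConfigError(ValueError):
    """Configuration is internally inconsistent or infeasible."""


@dataclass
class SyntheticConfig:
    """All knobs of the generator; a fixed seed fixes every output bit-identically."""

    genome_length: int = 200_000
    n_chroms: int = 1
    sat2_arrays: int = 5
    sat2_units: tuple[int, int] = (60, 90)
    sat3_arrays: int = 5
    sat3_units: tuple[int, int] = (35, 55)
    n_pos_nucs: int = 50
    n_neg_nucs: int = 50
    reads_per_nuc: float = 40.0
    background_rate: float = 0.001
    dup_rate: float = 0.06
    start_jitter_sd: float = 5.0
    read_length: int = 25
    depth_multipliers: dict[str, float] = field(default_factory=dict)
    coloc_map: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"H4K20me3": ("pos", 10.0), "H3K9me3": ("pos", 6.0)}
    )
    feature_channels: list[str] = field(
        default_factory=lambda: list(DEFAULT_FEATURE_CHANNELS)
    )
    pos_mark: str = "H4R3me2s"
    neg_mark: str = "H2AZ"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.genome_length, self.n_chroms, self.sat2_arrays, self.sat3_arrays,
            self.n_pos_nucs, self.n_neg_nucs,
        )
        if any(c < 0 for c in counts):
            raise SyntheticConfigError("counts must be >= 0")
        if self.genome_length <= 0 or self.n_chroms <= 0:
            raise SyntheticConfigError("genome must be non-empty")
        if not (0.0 <= self.dup_rate <= 1.0):
            raise SyntheticConfigError("dup_rate must lie in [0, 1]")
        if self.reads_per_nuc < 0 or self.background_rate < 0:
            raise SyntheticConfigError("rates must be >= 0")
        if self.n_pos_nucs > 0 and self.sat2_arrays + self.sat3_arrays == 0:
            raise SyntheticConfigError(
                "positive-class nucleosomes require at least one satellite array"
            )
        for channel, (class_key, intensity) in self.coloc_map.items():
            if class_key not in ("pos", "neg"):
                raise SyntheticConfigError(
                    f"coloc_map[{channel!r}] references unknown class {class_key!r}"
                )
            if intensity < 0:
                raise SyntheticConfigError("coloc intensity must be >= 0")
            if channel not in self.feature_channels:
                raise SyntheticConfigError(
                    f"coloc_map channel {channel!r} not among feature_channels"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.genome_length for i in range(self.n_chroms)}

    def mark_for_class(self, class_key: str) -> str:
        return {"pos": self.pos_mark, "neg": self.neg_mark}[class_key]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted stable nucleosome (147 bp)."""

    interval: GenomicInterval
    label: str
    repeat_family: str | None = None

    def __post_init__(self) -> None:
        if self.interval.width != NUCLEOSOME_WIDTH:
            raise ValueError(
                f"truth interval must be {NUCLEOSOME_WIDTH} bp, got {self.interval.width}"
            )


def _rng(config: SyntheticConfig, *key: str) -> np.random.Generator:
    # crc32-keyed streams: stable across processes, independent per purpose.
    return np.random.default_rng(
        [config.seed % (2**31), *(zlib.crc32(k.encode()) for k in key)]
    )


def _sat2_unit(rng: np.random.Generator) -> str:
    return SAT2_CORE * 2 + SAT2_SPACER * int(rng.integers(1, 3))


def _sat3_unit(rng: np.random.Generator) -> str:
    return SAT3_CORE * int(rng.integers(7, 14)) + SAT3_SPACER


def _place(
    rng: np.random.Generator,
    length: int,
    chrom_names: Sequence[str],
    chrom_len: int,
    occupied: dict[str, list[tuple[int, int]]],
    margin: int,
    attempts: int = 2000,
) -> GenomicInterval:
    for _ in range(attempts):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        if chrom_len - length <= 0:
            continue
        start = int(rng.integers(0, chrom_len - length))
        lo, hi = start - margin, start + length + margin
        if all(e <= lo or s >= hi for s, e in occupied[chrom]):
            occupied[chrom].append((start, start + length))
            return GenomicInterval(chrom, start, start + length)
    raise SyntheticConfigError(
        "could not place all arrays/nucleosomes; genome too small for config"
    )


def build_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[RepeatAnnotation], list[TruthRecord]]:
    """Generate the genome, its repeat annotations and the planted truth.

    Background sequence is i.i.d. uniform ACGT; satellite arrays overwrite
    it and are annotated exactly; positive-class nucleosomes are placed
    inside satellite arrays, negative-class nucleosomes in background, all
    mutually non-overlapping with generous spacing so planted peaks stay
    resolvable.
    """
    rng = _rng(config, "genome")
    chrom_names = list(config.chrom_lengths)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom_arrays = {
        c: alphabet[rng.integers(0, 4, size=config.genome_length)]
        for c in chrom_names
    }

    array_specs: list[tuple[str, str]] = []
    for _ in range(config.sat2_arrays):
        units = int(rng.integers(config.sat2_units[0], config.sat2_units[1] + 1))
        array_specs.append(("HSATII", "".join(_sat2_unit(rng) for _ in range(units))))
    for i in range(config.sat3_arrays):
        units = int(rng.integers(config.sat3_units[0], config.sat3_units[1] + 1))
        name = "(CATTC)n" if i % 2 == 0 else "(GAATG)n"
        array_specs.append((name, "".join(_sat3_unit(rng) for _ in range(units))))

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    annotations: list[RepeatAnnotation] = []
    arrays: list[tuple[GenomicInterval, str]] = []
    for rep_name, seq in array_specs:
        iv = _place(rng, len(seq), chrom_names, config.genome_length, occupied, margin=400)
        chrom_arrays[iv.chrom][iv.start : iv.end] = np.frombuffer(
            seq.encode(), dtype=np.uint8
        )
        annotations.append(RepeatAnnotation(iv, rep_name, "Satellite"))
        arrays.append((iv, rep_name))

    truth: list[TruthRecord] = []
    nuc_occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    # Positive-class nucleosomes fill non-overlapping slots inside the arrays,
    # spaced >= 150 bp apart so neighbouring planted peaks stay resolvable.
    slot_pool: list[tuple[GenomicInterval, str]] = []
    spacing = NUCLEOSOME_WIDTH + 150
    for iv_arr, rep_name in arrays:
        cursor = iv_arr.start + int(rng.integers(0, 30))
        while cursor + NUCLEOSOME_WIDTH <= iv_arr.end:
            slot_pool.append(
                (
                    GenomicInterval(iv_arr.chrom, cursor, cursor + NUCLEOSOME_WIDTH),
                    rep_name,
                )
            )
            cursor += spacing
    if config.n_pos_nucs > len(slot_pool):
        raise SyntheticConfigError(
            f"satellite arrays hold only {len(slot_pool)} nucleosome slots; "
            f"{config.n_pos_nucs} positive-class nucleosomes requested"
        )
    chosen = rng.choice(len(slot_pool), size=config.n_pos_nucs, replace=False)
    for i in sorted(chosen.tolist()):
        iv, rep_name = slot_pool[i]
        nuc_occupied[iv.chrom].append((iv.start, iv.end))
        truth.append(TruthRecord(iv, config.pos_mark, rep_name))
    for c in chrom_names:
        # keep negatives out of the satellite arrays as well
        nuc_occupied[c].extend(occupied[c])
    for _ in range(config.n_neg_nucs):
        iv = _place(
            rng, NUCLEOSOME_WIDTH, chrom_names, config.genome_length,
            nuc_occupied, margin=200,
        )
        truth.append(TruthRecord(iv, config.neg_mark, None))

    genome = {c: arr.tobytes().decode() for c, arr in chrom_arrays.items()}
    annotations.sort(key=lambda a: (a.interval.chrom, a.interval.start))
    return genome, annotations, truth


def _emit_sample(
    rng: np.random.Generator,
    config: SyntheticConfig,
    nucleosomes: Sequence[GenomicInterval],
    signal_per_nuc: float,
    depth: float,
) -> list[Read]:
    """Signal + background + PCR duplication for one sample."""
    L = config.genome_length
    rl = config.read_length
    chrom_names = list(config.chrom_lengths)
    reads: list[Read] = []
    for iv in nucleosomes:
        n_plus = int(rng.poisson(signal_per_nuc * depth / 2.0))
        plus_5p = np.rint(
            rng.normal(iv.start - 1, config.start_jitter_sd, size=n_plus)
        ).astype(int)
        plus_5p = np.clip(plus_5p, 0, L - rl)
        # mirrored count on the minus strand at the 3' edge
        minus_5p = np.rint(
            rng.normal(iv.end, config.start_jitter_sd, size=n_plus)
        ).astype(int)
        minus_5p = np.clip(minus_5p, rl - 1, L - 1)
        for p in plus_5p:
            reads.append(Read(iv.chrom, int(p), int(p) + rl, "+"))
        for p in minus_5p:
            reads.append(Read(iv.chrom, int(p) - rl + 1, int(p) + 1, "-"))
    n_bg = int(rng.poisson(config.background_rate * L * len(chrom_names) * depth))
    bg_chroms = rng.integers(0, len(chrom_names), size=n_bg)
    bg_starts = rng.integers(0, L - rl, size=n_bg)
    bg_strands = rng.integers(0, 2, size=n_bg)
    for ci, s, st in zip(bg_chroms, bg_starts, bg_strands):
        reads.append(
            Read(chrom_names[ci], int(s), int(s) + rl, "+" if st == 0 else "-")
        )
    out: list[Read] = []
    for read in reads:
        out.append(read)
        if config.dup_rate > 0 and rng.random() < config.dup_rate:
            out.append(read)
    return out


def simulate_reads(
    config: SyntheticConfig, truth: Sequence[TruthRecord], mark: str
) -> list[Read]:
    """Simulate the BED read set of one outcome mark (``pos_mark`` or ``neg_mark``)."""
    if mark not in (config.pos_mark, config.neg_mark):
        raise ValueError(f"unknown outcome mark {mark!r}")
    rng = _rng(config, "reads", mark)
    nucs = [rec.interval for rec in truth if rec.label == mark]
    depth = config.depth_multipliers.get(mark, 1.0)
    return _emit_sample(rng, config, nucs, config.reads_per_nuc, depth)


def simulate_feature_channels(
    config: SyntheticConfig, truth: Sequence[TruthRecord]
) -> dict[str, list[Read]]:
    """Simulate every feature-modification channel.

    Channels listed in ``coloc_map`` emit signal reads at the nucleosomes of
    their mapped class at their mapped intensity (plus background); unmapped
    channels emit uniform background only.
    """
    channels: dict[str, list[Read]] = {}
    for name in config.feature_channels:
        rng = _rng(config, "feature", name)
        depth = config.depth_multipliers.get(name, 1.0)
        if name in config.coloc_map:
            class_key, intensity = config.coloc_map[name]
            mark = config.mark_for_class(class_key)
            nucs = [rec.interval for rec in truth if rec.label == mark]
        else:
            nucs, intensity = [], 0.0
        channels[name] = _emit_sample(rng, config, nucs, intensity, depth)
    return channels


@dataclass
class SyntheticDataset:
    """One fully generated study: genome, truth and all read sets."""

    config: SyntheticConfig
    genome: dict[str, str]
    annotations: list[RepeatAnnotation]
    truth: list[TruthRecord]
    outcome_reads: dict[str, list[Read]]
    feature_reads: dict[str, list[Read]]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    genome, annotations, truth = build_genome(config)
    outcome = {
        mark: simulate_reads(config, truth, mark)
        for mark in (config.pos_mark, config.neg_mark)
    }
    features = simulate_feature_channels(config, truth)
    return SyntheticDataset(config, genome, annotations, truth, outcome, features)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write FASTA genome, per-mark BED6 read files, BED annotations and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, outdir / "genome.fa")
    write_repeat_bed(dataset.annotations, outdir / "repeats.bed")
    for mark, reads in dataset.outcome_reads.items():
        write_bed(reads, outdir / f"{mark}.bed")
    feature_dir = outdir / "features"
    feature_dir.mkdir(exist_ok=True)
    for name, reads in dataset.feature_reads.items():
        write_bed(reads, feature_dir / f"{name}.bed")
    rows = [
        {
            "chrom": rec.interval.chrom,
            "start": rec.interval.start,
            "end": rec.interval.end,
            "label": rec.label,
            "repeat_family": rec.repeat_family or ".",
        }
        for rec in dataset.truth
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)


__all__ = [
    "SyntheticConfig",
    "SyntheticConfigError",
    "SyntheticDataset",
    "TruthRecord",
    "DEFAULT_FEATURE_CHANNELS",
    "build_genome",
    "simulate_reads",
    "simulate_feature_channels",
    "generate_dataset",
    "write_dataset",
    "replace",
]
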