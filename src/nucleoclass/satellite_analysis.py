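"""Downstream interpretation of called nucleosomes against repeat annotations.

Three statistics connect elicited features back to genome biology:

* per-sequence occurrence histograms of a motif (e.g. TCCATT) in
  nucleosome-bound DNA,
* the repeat-family composition of each mark's stable-nucleosome-bound
  base pairs (what fraction of bound DNA is satellite II, satellite III,
  ...), and
* occupancy profiles over start-aligned repeat instances: at each offset,
  the fraction of instances covered there by a stable nucleosome of the
  mark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomicInterval, RepeatAnnotation
from .nucleosome_calling import NucleosomePeak

#: RepeatMasker-style repName groupings for the two pericentromeric satellites.
DEFAULT_FAMILIES: dict[str, frozenset[str]] = {
    "satellite II": frozenset({"HSATII"}),
    "satellite III": frozenset({"(CATTC)n", "(GAATG)n"}),
}


@dataclass
class MotifHistogram:
    """Distribution over sequences of exact forward-strand motif occurrence counts."""

    histogram: dict[int, int]
    fraction_with_motif: float
    max_count: int
    median_count: float


@dataclass
class RepeatComposition:
    """Fraction of a mark's stable-nucleosome-bound bp in each repeat family."""

    mark: str
    fractions: dict[str, float]
    residual: float


@dataclass
class OccupancyProfile:
    """Per-offset occupancy over start-aligned repeat instances.

    ``occupancy[pos]`` is the fraction of instances whose bp at offset
    ``pos`` is covered by at least one canonical nucleosome of the mark,
    among instances long enough to have that offset.  ``summary`` is the
    mean occupancy over offsets up to the median instance length.
    """

    family: str
    occupancy: np.ndarray
    denominators: np.ndarray
    n_instances: int
    summary: float


def _as_interval(peak: NucleosomePeak | GenomicInterval) -> GenomicInterval:
    return peak.canonical if isinstance(peak, NucleosomePeak) else peak


def _merged_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def _union_bp(merged: Mapping[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for ivs in merged.values() for s, e in ivs)


def _intersection_bp(
    a: Mapping[str, list[tuple[int, int]]], b: Mapping[str, list[tuple[int, int]]]
) -> int:
    total = 0
    for chrom in a.keys() & b.keys():
        for s1, e1 in a[chrom]:
            for s2, e2 in b[chrom]:
                total += max(0, min(e1, e2) - max(s1, s2))
    return total


def motif_occurrence_histogram(
    sequences: Mapping[str, str] | Sequence[str], motif: str
) -> MotifHistogram:
    """Exact overlapping-scan occurrence histogram of a motif over sequences.

    Counts are forward-strand, zero-mismatch, position-by-position (so
    overlapping occurrences all count).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    counts = []
    k = len(motif)
    for seq in seqs:
        counts.append(sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == motif))
    histogram: dict[int, int] = {}
    for c in counts:
        histogram[c] = histogram.get(c, 0) + 1
    n = len(counts)
    return MotifHistogram(
        histogram,
        (sum(1 for c in counts if c >= 1) / n) if n else 0.0,
        max(counts) if counts else 0,
        float(np.median(counts)) if counts else 0.0,
    )


def repeat_composition(
    peaks_by_mark: Mapping[str, Sequence[NucleosomePeak | GenomicInterval]],
    annotations: Sequence[RepeatAnnotation],
    families: Mapping[str, frozenset[str]] = DEFAULT_FAMILIES,
) -> dict[str, RepeatComposition]:
    """Fraction of each mark's bound bp overlapping each repeat family.

    Bound DNA is the *union* of the mark's canonical intervals (a set of
    bp, not a multiset), and family intervals are unioned likewise, so
    overlaps never double-count.
    """
    family_merged = {
        fam: _merged_by_chrom(
            ann.interval for ann in annotations if ann.rep_name in names
        )
        for fam, names in families.items()
    }
    out: dict[str, RepeatComposition] = {}
    for mark, peaks in peaks_by_mark.items():
        bound = _merged_by_chrom(_as_interval(pk) for pk in peaks)
        total = _union_bp(bound)
        fractions = {}
        for fam, merged in family_merged.items():
            fractions[fam] = (
                _intersection_bp(bound, merged) / total if total else 0.0
            )
        out[mark] = RepeatComposition(mark, fractions, 1.0 - sum(fractions.values()))
    return out


def occupancy_profile(
    peaks: Sequence[NucleosomePeak | GenomicInterval],
    repeat_instances: Sequence[GenomicInterval],
    family: str = "",
) -> OccupancyProfile:
    """Occupancy of a mark over start-aligned repeat instances.

    Instances are aligned at their genomic start (annotations are
    strandless, so the genomic + direction is the alignment frame);
    offsets beyond a shorter instance's end are excluded from its
    denominator.
    """
    if not repeat_instances:
        raise ValueError("empty repeat instance set")
    merged = _merged_by_chrom(_as_interval(pk) for pk in peaks)
    L = max(iv.width for iv in repeat_instances)
    covered = np.zeros(L, dtype=float)
    denominators = np.zeros(L, dtype=int)
    for iv in repeat_instances:
        denominators[: iv.width] += 1
        for s, e in merged.get(iv.chrom, []):
            lo = max(s, iv.start) - iv.start
            hi = min(e, iv.end) - iv.start
            if hi > lo:
                covered[lo:hi] += 1
    with np.errstate(invalid="ignore"):
        occupancy = np.where(denominators > 0, covered / np.maximum(denominators, 1), 0.0)
    median_len = int(np.median([iv.width for iv in repeat_instances]))
    summary = float(occupancy[:median_len].mean()) if median_len > 0 else 0.0
    return OccupancyProfile(family, occupancy, denominators, len(repeat_instances), summary)
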