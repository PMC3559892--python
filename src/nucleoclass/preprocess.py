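"""Read deduplication and depth normalization.

ChIP-Seq libraries carry PCR duplicates (identical 5' ends on the same
strand) and sample-to-sample depth variation.  Both bias peak calling, so
the pipeline collapses duplicates to single reads and then down-samples
every sample to the smallest unique-read count across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import Read


@dataclass(frozen=True)
class SampleStats:
    """Per-sample read counts before/after duplicate collapsing."""

    name: str
    n_total: int
    n_unique: int

    def __post_init__(self) -> None:
        if self.n_unique > self.n_total:
            raise ValueError("n_unique cannot exceed n_total")

    @property
    def duplicate_fraction(self) -> float:
        """Fraction of input reads that were duplicates: ``1 - n_unique / n_total``."""
        if self.n_total == 0:
            return 0.0
        return 1.0 - self.n_unique / self.n_total


def deduplicate(
    reads: Sequence[Read], name: str = "sample"
) -> tuple[list[Read], SampleStats]:
    """Collapse duplicate reads into single reads.

    The duplicate key is ``(chrom, start, strand)``: with fixed-length
    single-end reads the 5' end identifies the sequenced fragment, which is
    the standard PCR-duplicate criterion.  Exactly one read is retained per
    key (the first seen) and the output is sorted by (chrom, start, strand)
    for determinism.
    """
    seen: dict[tuple[str, int, str], Read] = {}
    for read in reads:
        key = (read.chrom, read.start, read.strand)
        if key not in seen:
            seen[key] = read
    unique = sorted(seen.values(), key=lambda r: (r.chrom, r.start, r.strand))
    return unique, SampleStats(name, len(reads), len(unique))


def normalize_depth(
    samples: Mapping[str, Sequence[Read]], seed: int
) -> dict[str, list[Read]]:
    """Down-sample every sample to the minimum unique-read count.

    Sampling is uniform without replacement, seeded; samples already at the
    minimum size pass through unchanged.  Samples are processed in sorted
    name order so the result does not depend on mapping insertion order.
    """
    if not samples:
        raise ValueError("no samples given")
    for name, reads in samples.items():
        if len(reads) == 0:
            raise ValueError(f"sample {name!r} is empty; minimum depth undefined")
    target = min(len(reads) for reads in samples.values())
    rng = np.random.default_rng(seed)
    out: dict[str, list[Read]] = {}
    for name in sorted(samples):
        reads = samples[name]
        if len(reads) == target:
            out[name] = list(reads)
        else:
            idx = np.sort(rng.choice(len(reads), size=target, replace=False))
            out[name] = [reads[i] for i in idx]
    return out
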