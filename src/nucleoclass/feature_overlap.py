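"""Histone-modification feature arrays via strand-specific boundary overlap.

For each stable (outcome) nucleosome and each feature modification, the
entry is the number of deduplicated feature reads that co-localize with the
nucleosome boundaries in a strand-specific manner: a '+' read is counted
when its 5' end lies within +/- 50 bp of the nucleosome's 5' (canonical
start) boundary, a '-' read when its 5' end lies within +/- 50 bp of the 3'
(canonical end - 1) boundary.  Both window bounds are inclusive, giving a
closed 101-bp window per boundary.

Counts (rather than binary stable-nucleosome overlap) give a richer, less
sparse matrix.  Feature reads are expected deduplicated; depth
normalization of feature channels is left to the caller.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import LABEL_COLUMN, GenomicInterval, Read
from .nucleosome_calling import NucleosomePeak

BOUNDARY_WINDOW = 50


def _five_prime_arrays(reads: Sequence[Read]) -> tuple[np.ndarray, np.ndarray]:
    plus = np.sort(np.array([r.start for r in reads if r.strand == "+"], dtype=int))
    minus = np.sort(np.array([r.end - 1 for r in reads if r.strand == "-"], dtype=int))
    return plus, minus


def _count_in_closed(sorted_positions: np.ndarray, lo: int, hi: int) -> int:
    return int(
        np.searchsorted(sorted_positions, hi, side="right")
        - np.searchsorted(sorted_positions, lo, side="left")
    )


def score_overlap(
    nucleosome: NucleosomePeak | GenomicInterval,
    feature_reads: Sequence[Read],
    window: int = BOUNDARY_WINDOW,
) -> int:
    """Strand-specific boundary overlap count for one nucleosome.

    ``+`` reads with start in ``[canonical.start - window, canonical.start +
    window]`` plus ``-`` reads with 5' end in ``[canonical.end - 1 - window,
    canonical.end - 1 + window]`` (closed bounds).
    """
    canonical = nucleosome.canonical if isinstance(nucleosome, NucleosomePeak) else nucleosome
    plus, minus = _five_prime_arrays(feature_reads)
    return _score_from_arrays(canonical, plus, minus, window)


def _score_from_arrays(
    canonical: GenomicInterval, plus: np.ndarray, minus: np.ndarray, window: int
) -> int:
    five = canonical.start
    three = canonical.end - 1
    return _count_in_closed(plus, five - window, five + window) + _count_in_closed(
        minus, three - window, three + window
    )


def nucleosome_row_id(label: str, canonical: GenomicInterval) -> str:
    return f"{label}|{canonical.chrom}:{canonical.start}-{canonical.end}"


def build_matrix(
    outcome_peaks_by_class: Mapping[str, Sequence[NucleosomePeak]],
    feature_samples: Mapping[str, Sequence[Read]] | Sequence[tuple[str, Sequence[Read]]],
    window: int = BOUNDARY_WINDOW,
) -> pd.DataFrame:
    """Build the labeled modification feature matrix.

    One row per outcome nucleosome (row id encodes class and canonical
    interval; rows ordered by class, chrom, start), a ``label`` column with
    the outcome class, and one integer count column per feature sample, in
    the supplied order.  Duplicate feature sample names are a config error.
    """
    if isinstance(feature_samples, Mapping):
        items = list(feature_samples.items())
    else:
        items = list(feature_samples)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature sample names")

    rows: list[tuple[str, str, GenomicInterval]] = []
    for label in sorted(outcome_peaks_by_class):
        peaks = sorted(
            outcome_peaks_by_class[label],
            key=lambda p: (p.canonical.chrom, p.canonical.start),
        )
        for pk in peaks:
            rows.append((nucleosome_row_id(label, pk.canonical), label, pk.canonical))

    arrays = {name: _five_prime_arrays(reads) for name, reads in items}
    data = {
        name: np.array(
            [_score_from_arrays(iv, *arrays[name], window) for _, _, iv in rows],
            dtype=int,
        )
        for name in names
    }
    matrix = pd.DataFrame(data, index=[rid for rid, _, _ in rows])
    matrix.insert(0, LABEL_COLUMN, [label for _, label, _ in rows])
    matrix.index.name = "id"
    return matrix
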