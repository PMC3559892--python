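"""Discriminatory motif feature construction with a withheld discovery set.

Sequence features are built in two strictly separated stages to avoid data
reusage: a *discovery* partition (a stratified fraction ``f`` of each
class, default 0.2) is used to elicit at most 300 discriminatory motifs of
length 5-10, and the disjoint *classification* partition receives
mismatch-tolerant motif match-count features for downstream classification.
Feeding discovery sequences back into the feature matrix raises
:class:`DataLeakageError`.

Motif elicitation scores every k-mer observed in the discovery data (a
k-mer and its reverse complement are one candidate; presence is counted
once per sequence regardless of strand or multiplicity) by the two-sample
proportion z-statistic between classes.  Candidates are ranked by |z|;
ties are broken by length (longer first: at equal discrimination a longer
motif is more specific), then by occurrence abundance in the favored
class, then lexicographically.  Any candidate that is a substring (in
either orientation) of a retained higher-ranked candidate is dropped as
redundant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import LABEL_COLUMN, reverse_complement

logger = logging.getLogger(__name__)

DNA = frozenset("ACGT")


class DataLeakageError(ValueError):
    """Discovery sequences leaked into the classification feature matrix."""


@dataclass(frozen=True)
class PartitionSpec:
    """Stratified discovery/classification split specification."""

    discovery_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.discovery_fraction < 1.0):
            raise ValueError("discovery_fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class Motif:
    """An elicited discriminatory k-mer (canonical strand orientation)."""

    sequence: str
    score: float
    direction: str
    class_fractions: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if set(self.sequence) - DNA:
            raise ValueError("motif must be uppercase ACGT")

    @property
    def length(self) -> int:
        return len(self.sequence)


SequenceSet = Mapping[str, Mapping[str, str]]  # label -> {sequence id -> sequence}


def partition(
    sequences_by_class: SequenceSet, spec: PartitionSpec
) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, str]]]:
    """Stratified split into disjoint (discovery, classification) sets."""
    rng = np.random.default_rng(spec.seed)
    discovery: dict[str, dict[str, str]] = {}
    classification: dict[str, dict[str, str]] = {}
    for label in sorted(sequences_by_class):
        seqs = sequences_by_class[label]
        ids = sorted(seqs)
        n = len(ids)
        if n < 2:
            raise ValueError(f"class {label!r} needs >= 2 sequences to partition")
        n_disc = min(max(int(round(spec.discovery_fraction * n)), 1), n - 1)
        chosen = set(rng.choice(n, size=n_disc, replace=False).tolist())
        discovery[label] = {ids[i]: seqs[ids[i]] for i in range(n) if i in chosen}
        classification[label] = {ids[i]: seqs[ids[i]] for i in range(n) if i not in chosen}
    return discovery, classification


def canonical_kmer(kmer: str) -> str:
    """Strand-canonical representative: the lexicographic min of kmer/revcomp."""
    return min(kmer, reverse_complement(kmer))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pooled two-sample proportion z-statistic; 0 when the pooled rate is degenerate."""
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    return (p1 - p2) / se


def elicit_motifs(
    discovery: SequenceSet,
    l_min: int = 5,
    l_max: int = 10,
    max_motifs: int = 300,
    min_support: float = 0.05,
    min_abs_z: float = 0.0,
) -> list[Motif]:
    """Elicit at most ``max_motifs`` discriminatory motifs from the discovery set.

    A candidate must be present in at least ``min_support`` of one class's
    sequences; candidates with |z| <= ``min_abs_z`` are discarded.  With the
    default mismatch tolerance of 2 downstream, 5-mers are permissive
    matchers — a warning is logged when they are elicited.
    """
    labels = sorted(discovery)
    if len(labels) != 2:
        raise ValueError(f"exactly two classes required, got {labels}")
    for label in labels:
        if not discovery[label]:
            raise ValueError(f"discovery class {label!r} is empty")
    lab_a, lab_b = labels
    n_a, n_b = len(discovery[lab_a]), len(discovery[lab_b])

    presence: dict[str, list[int]] = {}
    abundance: dict[str, list[int]] = {}
    for ci, label in enumerate(labels):
        for seq in discovery[label].values():
            seen: set[str] = set()
            for k in range(l_min, l_max + 1):
                for i in range(len(seq) - k + 1):
                    window = seq[i : i + k]
                    if set(window) - DNA:
                        continue
                    canon = canonical_kmer(window)
                    abundance.setdefault(canon, [0, 0])[ci] += 1
                    seen.add(canon)
            for canon in seen:
                presence.setdefault(canon, [0, 0])[ci] += 1

    floor_a = min_support * n_a
    floor_b = min_support * n_b
    scored: list[tuple[float, int, int, str, float, float, float]] = []
    for canon, (c_a, c_b) in presence.items():
        if c_a < floor_a and c_b < floor_b:
            continue
        z = two_proportion_z(c_a, n_a, c_b, n_b)
        if abs(z) <= min_abs_z:
            continue
        occ = abundance[canon]
        favored_occ = occ[0] if z > 0 else occ[1]
        scored.append((abs(z), favored_occ, len(canon), canon, z, c_a / n_a, c_b / n_b))

    scored.sort(key=lambda t: (-t[0], -t[2], -t[1], t[3]))
    retained: list[Motif] = []
    retained_seqs: list[str] = []
    for _, _, _, canon, z, frac_a, frac_b in scored:
        rc = reverse_complement(canon)
        if any(canon in kept or rc in kept for kept in retained_seqs):
            continue
        direction = lab_a if z > 0 else lab_b
        retained.append(
            Motif(canon, z, direction, ((lab_a, frac_a), (lab_b, frac_b)))
        )
        retained_seqs.append(canon)
        if len(retained) >= max_motifs:
            break
    if any(m.length == 5 for m in retained):
        logger.warning(
            "5-mers elicited: with 2 mismatches allowed downstream these match "
            "a large fraction of random windows"
        )
    return retained


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def match_count(sequence: str, motif: str, max_mismatches: int = 2) -> int:
    """Number of windows of ``len(motif)`` in the sequence (forward strand)
    plus in its reverse complement whose Hamming distance to the motif is
    at most ``max_mismatches``.  Overlapping windows all count; a motif
    longer than the sequence yields 0.
    """
    k = len(motif)
    if k == 0:
        raise ValueError("motif must be non-empty")
    if k > len(sequence):
        return 0
    m = _encode(motif)
    total = 0
    for strand_seq in (sequence, reverse_complement(sequence)):
        windows = np.lib.stride_tricks.sliding_window_view(_encode(strand_seq), k)
        mismatches = (windows != m).sum(axis=1)
        total += int(np.count_nonzero(mismatches <= max_mismatches))
    return total


def build_motif_matrix(
    classification_set: SequenceSet,
    motifs: Sequence[Motif],
    max_mismatches: int = 2,
    discovery_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Mismatch-tolerant motif count matrix over the classification set.

    Raises :class:`DataLeakageError` if any row id also appears in
    ``discovery_ids`` (pass the discovery partition's ids to arm the guard).
    """
    rows: list[tuple[str, str, str]] = []
    for label in sorted(classification_set):
        for sid in sorted(classification_set[label]):
            rows.append((sid, label, classification_set[label][sid]))
    if discovery_ids:
        leaked = discovery_ids & {sid for sid, _, _ in rows}
        if leaked:
            raise DataLeakageError(
                f"{len(leaked)} discovery sequences appear in the classification set"
            )
    data = {
        motif.sequence: np.array(
            [match_count(seq, motif.sequence, max_mismatches) for _, _, seq in rows],
            dtype=int,
        )
        for motif in motifs
    }
    matrix = pd.DataFrame(data, index=[sid for sid, _, _ in rows])
    matrix.insert(0, LABEL_COLUMN, [label for _, label, _ in rows])
    matrix.index.name = "id"
    return matrix


def write_motifs(motifs: Sequence[Motif], path) -> None:
    rows = []
    for m in motifs:
        row = {"motif": m.sequence, "length": m.length, "z": m.score, "direction": m.direction}
        for label, frac in m.class_fractions:
            row[f"presence_{label}"] = frac
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
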