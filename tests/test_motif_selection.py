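"""Discovery/classification partitioning, motif elicitation and matching."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoclass.io_formats import reverse_complement
from nucleoclass.motif_selection import (
    DataLeakageError,
    Motif,
    PartitionSpec,
    build_motif_matrix,
    canonical_kmer,
    elicit_motifs,
    match_count,
    partition,
    two_proportion_z,
)


def _random_seqs(n, length, rng, label):
    return {
        f"{label}{i}": "".join(rng.choice(list("ACGT"), size=length)) for i in range(n)
    }


class TestPartition:
    def test_stratified_sizes_at_f_02(self):
        rng = np.random.default_rng(0)
        data = {"p": _random_seqs(100, 30, rng, "p"), "n": _random_seqs(100, 30, rng, "n")}
        disc, clas = partition(data, PartitionSpec(0.2, seed=1))
        assert {k: len(v) for k, v in disc.items()} == {"p": 20, "n": 20}
        assert {k: len(v) for k, v in clas.items()} == {"p": 80, "n": 80}

    def test_minimal_split_half_and_half(self):
        data = {"p": {"a": "ACGT", "b": "TTTT"}, "n": {"c": "GGGG", "d": "CCCC"}}
        disc, clas = partition(data, PartitionSpec(0.5, seed=0))
        assert all(len(v) == 1 for v in disc.values())
        assert all(len(v) == 1 for v in clas.values())

    def test_split_is_seeded_and_disjoint(self):
        rng = np.random.default_rng(3)
        data = {"p": _random_seqs(40, 20, rng, "p"), "n": _random_seqs(40, 20, rng, "n")}
        first = partition(data, PartitionSpec(0.2, seed=5))
        second = partition(data, PartitionSpec(0.2, seed=5))
        assert first == second
        for label in data:
            assert not (set(first[0][label]) & set(first[1][label]))

    def test_tiny_class_is_an_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            partition({"p": {"a": "ACGT"}, "n": {"b": "ACGT", "c": "ACGT"}},
                      PartitionSpec(0.2, seed=0))

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PartitionSpec(0.0, seed=0)


def test_two_proportion_z_matches_statsmodels_oracle():
    from statsmodels.stats.proportion import proportions_ztest

    expected, _ = proportions_ztest([18, 2], [20, 20])
    assert two_proportion_z(18, 20, 2, 20) == pytest.approx(expected, rel=1e-12)


class TestElicitMotifs:
    def test_planted_motif_ranks_first_with_positive_direction(self):
        rng = np.random.default_rng(2)
        pos = {
            sid: seq[:10] + "TCCATT" + seq[16:]
            for sid, seq in _random_seqs(20, 40, rng, "p").items()
        }
        neg = {
            sid: seq.replace("TCCATT", "TCAATT")
            for sid, seq in _random_seqs(20, 40, rng, "n").items()
        }
        motifs = elicit_motifs({"pos": pos, "neg": neg})
        top = motifs[0]
        assert top.direction == "pos"
        target = canonical_kmer("TCCATT")
        assert target in top.sequence or reverse_complement(target) in top.sequence

    def test_identical_classes_yield_no_motifs(self):
        rng = np.random.default_rng(4)
        seqs = _random_seqs(10, 40, rng, "s")
        motifs = elicit_motifs({"a": seqs, "b": dict(seqs)})
        assert motifs == []

    def test_bounds_on_count_and_length(self, small_dataset):
        from nucleoclass.io_formats import extract_sequence

        by_class: dict[str, dict[str, str]] = {}
        for i, rec in enumerate(small_dataset.truth):
            by_class.setdefault(rec.label, {})[f"s{i}"] = extract_sequence(
                small_dataset.genome, rec.interval
            )
        motifs = elicit_motifs(by_class)
        assert len(motifs) <= 300
        assert all(5 <= m.length <= 10 for m in motifs)

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            elicit_motifs({"a": {}, "b": {"x": "ACGTACGT"}})


def _oracle_match_count(seq, motif, m):
    # exhaustive window scan, independent of the numpy implementation
    total = 0
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - len(motif) + 1):
            if sum(a != b for a, b in zip(s[i : i + len(motif)], motif)) <= m:
                total += 1
    return total


class TestMatchCount:
    def test_exact_self_match(self):
        assert match_count("TCCATT", "TCCATT", 0) == 1

    def test_revcomp_window_beyond_mismatch_budget_not_counted(self):
        # reverse complement AATGGA is Hamming distance 5 from TCCATT
        assert match_count("TCCATT", "TCCATT", 2) == 1

    def test_motif_longer_than_sequence_is_zero(self):
        assert match_count("ACG", "ACGTACGT", 2) == 0

    def test_overlapping_windows_all_count(self):
        # 3 overlapping forward windows; revcomp TTTTTT contributes none at M=0
        assert match_count("AAAAAA", "AAAA", 0) == 3
        # both strands contribute when each carries a window within budget
        assert match_count("AAAATTTT", "AAAA", 0) == 1 + 1

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            motif = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 11))))
            m = int(rng.integers(0, 3))
            assert match_count(seq, motif, m) == _oracle_match_count(seq, motif, m)


@settings(derandomize=True, max_examples=60)
@given(
    seq=st.text(alphabet="ACGT", min_size=8, max_size=50),
    motif=st.text(alphabet="ACGT", min_size=5, max_size=8),
    m=st.integers(min_value=0, max_value=2),
)
def test_match_count_reverse_complement_symmetry(seq, motif, m):
    assert match_count(seq, motif, m) == match_count(reverse_complement(seq), motif, m)


class TestMotifMatrix:
    def test_zero_motifs_gives_label_only_matrix(self):
        matrix = build_motif_matrix({"a": {"x": "ACGTACGT"}, "b": {"y": "TTTTAAAA"}}, [])
        assert list(matrix.columns) == ["label"]
        assert len(matrix) == 2

    def test_leakage_guard_triggers_on_discovery_rows(self):
        rng = np.random.default_rng(5)
        data = {"p": _random_seqs(10, 30, rng, "p"), "n": _random_seqs(10, 30, rng, "n")}
        disc, clas = partition(data, PartitionSpec(0.2, seed=1))
        ids = {sid for seqs in disc.values() for sid in seqs}
        build_motif_matrix(clas, [], discovery_ids=ids)  # disjoint: fine
        with pytest.raises(DataLeakageError):
            build_motif_matrix(disc, [], discovery_ids=ids)

    def test_planted_column_separates_classes(self):
        rng = np.random.default_rng(6)
        pos = {
            sid: seq[:5] + "TCCATTCCATT" + seq[16:]
            for sid, seq in _random_seqs(15, 40, rng, "p").items()
        }
        neg = _random_seqs(15, 40, rng, "n")
        motif = Motif("TCCATT", 4.0, "p")
        matrix = build_motif_matrix({"p": pos, "n": neg}, [motif], max_mismatches=0)
        assert (
            matrix.loc[matrix.label == "p", "TCCATT"].mean()
            > matrix.loc[matrix.label == "n", "TCCATT"].mean()
        )


def test_motif_type_enforces_alphabet():
    with pytest.raises(ValueError):
        Motif("TCCANT", 1.0, "p")
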