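"""End-to-end orchestration over a synthetic dataset.

Runs the whole analysis — simulate, deduplicate, depth-normalize, call
stable nucleosomes, build modification and motif feature matrices,
classify with balanced random forests, permutation-test feature
importance, and compute satellite composition/occupancy — and returns a
JSON-serializable result dictionary.  With ``outdir`` set, every
intermediate table is written as TSV/BED/JSON; runs are deterministic
under a fixed config seed, byte-identical file for file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import satellite_analysis
from .classification import (
    ClassifierConfig,
    combine_matrices,
    permutation_test_importance,
    run_balanced_evaluation,
)
from .feature_overlap import build_matrix
from .io_formats import (
    GenomicInterval,
    extract_sequence,
    write_bed,
    write_feature_matrix,
)
from .motif_selection import (
    PartitionSpec,
    build_motif_matrix,
    elicit_motifs,
    partition,
    write_motifs,
)
from .nucleosome_calling import NucleosomePeak, call_nucleosomes, write_peaks
from .preprocess import deduplicate, normalize_depth
from .synthetic_data import SyntheticConfig, TruthRecord, generate_dataset, write_dataset


def midpoint_recovery_rate(
    truth: Sequence[TruthRecord],
    peaks: Sequence[NucleosomePeak],
    mark: str,
    tolerance: int = 20,
) -> float:
    """Fraction of planted nucleosome midpoints of ``mark`` recovered within
    ``tolerance`` bp by a called canonical midpoint."""
    planted = [rec.interval for rec in truth if rec.label == mark]
    if not planted:
        return 0.0
    mids = [
        (pk.canonical.chrom, pk.canonical.start + pk.canonical.width // 2)
        for pk in peaks
    ]
    hit = 0
    for iv in planted:
        target = iv.start + iv.width // 2
        if any(c == iv.chrom and abs(m - target) <= tolerance for c, m in mids):
            hit += 1
    return hit / len(planted)


def run_pipeline(
    config: SyntheticConfig,
    outdir: str | Path | None = None,
    *,
    n_tree: int = 500,
    n_balance_repeats: int = 10,
    n_permutations: int = 200,
    perm_n_tree: int = 50,
    discovery_fraction: float = 0.2,
    max_mismatches: int = 2,
) -> dict:
    """Run the full analysis on one synthetic study; see module docstring."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    dataset = generate_dataset(config)
    if out is not None:
        write_dataset(dataset, out / "data")

    # --- pre-processing: dedup everything, depth-normalize the outcome marks
    stats = {}
    unique_outcome = {}
    for mark, reads in dataset.outcome_reads.items():
        unique, st = deduplicate(reads, mark)
        unique_outcome[mark] = unique
        stats[mark] = st
    unique_features = {}
    for name, reads in dataset.feature_reads.items():
        unique, st = deduplicate(reads, name)
        unique_features[name] = unique
        stats[name] = st
    normalized = normalize_depth(unique_outcome, seed=config.seed)
    if out is not None:
        rows = [
            {
                "sample": name,
                "total": st.n_total,
                "unique": st.n_unique,
                "duplicate_fraction": round(st.duplicate_fraction, 6),
                "retained": len(normalized.get(name, unique_features.get(name, []))),
            }
            for name, st in sorted(stats.items())
        ]
        pd.DataFrame(rows).to_csv(out / "preprocess_stats.tsv", sep="\t", index=False)

    # --- stable-nucleosome calling per outcome mark
    peaks_by_mark = {
        mark: call_nucleosomes(reads, config.chrom_lengths)
        for mark, reads in normalized.items()
    }
    recovery = {
        mark: midpoint_recovery_rate(dataset.truth, peaks, mark)
        for mark, peaks in peaks_by_mark.items()
    }
    if out is not None:
        for mark, peaks in peaks_by_mark.items():
            write_peaks(peaks, out / f"peaks_{mark}.bed")

    clf_config = ClassifierConfig(
        n_tree=n_tree,
        n_balance_repeats=n_balance_repeats,
        n_permutations=n_permutations,
        perm_n_tree=perm_n_tree,
        seed=config.seed,
    )

    # --- histone-modification features + classification
    mod_matrix = build_matrix(peaks_by_mark, unique_features)
    mod_eval = run_balanced_evaluation(mod_matrix, clf_config)
    from .classification import balance_downsample  # local to keep module surface tidy

    balanced = balance_downsample(mod_matrix, seed=config.seed)
    mod_perm = permutation_test_importance(balanced, clf_config)
    if out is not None:
        write_feature_matrix(mod_matrix, out / "modification_matrix.tsv")
        mod_perm.round(6).to_csv(out / "modification_importance.tsv", sep="\t")

    # --- DNA sequence features (discovery/classification split) + classification
    sequences = {
        mark: {
            f"{mark}|{pk.canonical.chrom}:{pk.canonical.start}-{pk.canonical.end}":
                extract_sequence(dataset.genome, pk.canonical)
            for pk in peaks
        }
        for mark, peaks in peaks_by_mark.items()
    }
    discovery, classification_set = partition(
        sequences, PartitionSpec(discovery_fraction, seed=config.seed)
    )
    motifs = elicit_motifs(discovery)
    discovery_ids = {sid for seqs in discovery.values() for sid in seqs}
    motif_matrix = build_motif_matrix(
        classification_set, motifs, max_mismatches, discovery_ids=discovery_ids
    )
    motif_eval = run_balanced_evaluation(motif_matrix, clf_config)
    if out is not None:
        write_motifs(motifs, out / "motifs.tsv")
        write_feature_matrix(motif_matrix, out / "motif_matrix.tsv")

    # --- combined classification on the shared (classification-set) rows
    combined_matrix = combine_matrices(
        mod_matrix.loc[motif_matrix.index], motif_matrix
    )
    combined_eval = run_balanced_evaluation(combined_matrix, clf_config)

    # --- downstream satellite statistics
    composition = satellite_analysis.repeat_composition(
        peaks_by_mark, dataset.annotations
    )
    sat2 = [a.interval for a in dataset.annotations if a.rep_name == "HSATII"]
    sat3 = [
        a.interval
        for a in dataset.annotations
        if a.rep_name in ("(CATTC)n", "(GAATG)n")
    ]
    occupancy = {}
    for mark, peaks in peaks_by_mark.items():
        occupancy[mark] = {}
        for fam, instances in (("satellite II", sat2), ("satellite III", sat3)):
            if instances:
                occupancy[mark][fam] = satellite_analysis.occupancy_profile(
                    peaks, instances, family=fam
                )
    tccatt = {
        mark: satellite_analysis.motif_occurrence_histogram(seqs, "TCCATT")
        for mark, seqs in sequences.items()
    }

    results = {
        "preprocessing": {
            name: {
                "total": st.n_total,
                "unique": st.n_unique,
                "duplicate_fraction": st.duplicate_fraction,
            }
            for name, st in sorted(stats.items())
        },
        "nucleosome_calling": {
            mark: {"n_peaks": len(peaks), "midpoint_recovery": recovery[mark]}
            for mark, peaks in peaks_by_mark.items()
        },
        "modification_classification": {
            "accuracy_mean": mod_eval.accuracy_mean,
            "accuracy_sd": mod_eval.accuracy_sd,
            "auroc_mean": mod_eval.auroc_mean,
            "auroc_sd": mod_eval.auroc_sd,
            "top_feature": mod_eval.mdg.idxmax(),
            "importance_p_adjusted": {
                k: float(v) for k, v in mod_perm["p_adjusted"].items()
            },
        },
        "sequence_classification": {
            "accuracy_mean": motif_eval.accuracy_mean,
            "accuracy_sd": motif_eval.accuracy_sd,
            "auroc_mean": motif_eval.auroc_mean,
            "auroc_sd": motif_eval.auroc_sd,
            "n_motifs": len(motifs),
            "top_motifs": [m.sequence for m in motifs[:20]],
        },
        "combined_classification": {
            "accuracy_mean": combined_eval.accuracy_mean,
            "auroc_mean": combined_eval.auroc_mean,
        },
        "satellite_analysis": {
            "composition": {
                mark: {**comp.fractions, "residual": comp.residual}
                for mark, comp in composition.items()
            },
            "occupancy_summary": {
                mark: {fam: prof.summary for fam, prof in fams.items()}
                for mark, fams in occupancy.items()
            },
            "tccatt_prevalence": {
                mark: hist.fraction_with_motif for mark, hist in tccatt.items()
            },
            "tccatt_max_count": {
                mark: hist.max_count for mark, hist in tccatt.items()
            },
        },
    }
    if out is not None:
        with open(out / "results.json", "w") as handle:
            json.dump(results, handle, indent=2, sort_keys=True)
        for mark, fams in occupancy.items():
            for fam, prof in fams.items():
                tag = fam.replace(" ", "_")
                pd.DataFrame(
                    {
                        "position": range(len(prof.occupancy)),
                        "occupancy": prof.occupancy.round(6),
                        "n_instances": prof.denominators,
                    }
                ).to_csv(out / f"occupancy_{tag}_{mark}.tsv", sep="\t", index=False)
    return results
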