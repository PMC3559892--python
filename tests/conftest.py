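"""Shared fixtures: small synthetic studies generated once per session."""

from __future__ import annotations

import pytest

from nucleoclass.nucleosome_calling import call_nucleosomes
from nucleoclass.preprocess import deduplicate, normalize_depth
from nucleoclass.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced study for fast unit tests: 60 kb genome, 12+12 nucleosomes."""
    return SyntheticConfig(
        genome_length=60_000,
        sat2_arrays=2,
        sat2_units=(50, 70),
        sat3_arrays=2,
        sat3_units=(30, 40),
        n_pos_nucs=12,
        n_neg_nucs=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    """The full study conditions: 200 kb genome, 50+50 planted nucleosomes."""
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def called_peaks(default_config, default_dataset):
    """Deduplicated, depth-normalized, called peaks for both outcome marks."""
    unique = {
        mark: deduplicate(reads, mark)[0]
        for mark, reads in default_dataset.outcome_reads.items()
    }
    normalized = normalize_depth(unique, seed=default_config.seed)
    return {
        mark: call_nucleosomes(reads, default_config.chrom_lengths)
        for mark, reads in normalized.items()
    }
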