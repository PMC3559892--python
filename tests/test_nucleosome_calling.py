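"""Pile-up, denoising, LoG edge detection, Poisson test and QC filtering."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nucleoclass.io_formats import Read
from nucleoclass.nucleosome_calling import (
    CoverageProfile,
    call_nucleosomes,
    denoise,
    detect_peaks,
    extend_and_pile,
    poisson_pvalue,
    qc_filter,
    score_candidates,
)
from nucleoclass.pipeline import midpoint_recovery_rate


class TestExtendAndPile:
    def test_plus_read_extends_3prime_to_150(self):
        profiles = extend_and_pile([Read("c", 1000, 1025, "+")], {"c": 2000})
        cov = profiles["c"].coverage
        assert cov[1000] == 1 and cov[1149] == 1
        assert cov[999] == 0 and cov[1150] == 0
        assert cov.sum() == 150

    def test_minus_read_extends_toward_5prime(self):
        profiles = extend_and_pile([Read("c", 1125, 1150, "-")], {"c": 2000})
        cov = profiles["c"].coverage
        assert cov[1000] == 1 and cov[1149] == 1
        assert cov[999] == 0 and cov[1150] == 0

    def test_stacked_reads_are_additive(self):
        reads = [Read("c", 500, 525, "+")] * 7
        cov = extend_and_pile(reads, {"c": 1000})["c"].coverage
        assert cov.max() == 7

    def test_extension_clipped_at_chromosome_end(self):
        cov = extend_and_pile([Read("c", 950, 975, "+")], {"c": 1000})["c"].coverage
        assert cov.sum() == 50

    def test_read_beyond_bounds_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            extend_and_pile([Read("c", 990, 1015, "+")], {"c": 1000})


@pytest.mark.parametrize("method", ["wavelet", "gaussian"])
class TestDenoise:
    def test_constant_profile_unchanged(self, method):
        x = np.full(1024, 5.0)
        y = denoise(x, method=method)
        assert np.allclose(y, x, rtol=0.01)

    def test_single_spike_conserves_mass(self, method):
        x = np.zeros(1024)
        x[512] = 100.0
        y = denoise(x, method=method)
        assert y.min() >= 0
        assert abs(y.sum() - x.sum()) <= 0.01 * x.sum()

    def test_two_spikes_400bp_apart_stay_distinct(self, method):
        x = np.zeros(2048)
        x[800] = x[1200] = 50.0
        y = denoise(x, method=method)
        left = int(np.argmax(y[:1000]))
        right = 1000 + int(np.argmax(y[1000:]))
        assert abs(left - 800) < 50 and abs(right - 1200) < 50
        trough = y[left:right].min()
        assert trough < 0.5 * min(y[left], y[right])


def test_denoise_rejects_bad_parameters():
    with pytest.raises(ValueError):
        denoise(np.zeros(64), method="gaussian", gaussian_sigma=0.0)
    with pytest.raises(ValueError):
        denoise(np.zeros(64), method="median")


class TestDetectPeaks:
    def test_flat_profile_has_no_peaks(self):
        assert detect_peaks(np.zeros(5000)) == []

    def test_single_gaussian_bump_gives_one_bracketing_peak(self):
        x = np.arange(5000, dtype=float)
        bump = 30.0 * np.exp(-0.5 * ((x - 2500) / 40.0) ** 2)
        peaks = detect_peaks(bump)
        assert len(peaks) == 1
        start, end = peaks[0]
        assert start < 2500 < end
        # LoG zero crossings of a Gaussian sit near +/- its combined SD
        sigma_eff = math.hypot(40.0, 25.0)
        assert abs((start + end) / 2 - 2500) < 5
        assert 1.2 * sigma_eff < (end - start) < 3.0 * sigma_eff

    def test_two_separated_bumps_give_two_ordered_peaks(self):
        x = np.arange(8000, dtype=float)
        bump = lambda mu: 30.0 * np.exp(-0.5 * ((x - mu) / 40.0) ** 2)
        peaks = detect_peaks(bump(2000) + bump(5000))
        assert len(peaks) == 2
        assert peaks[0][1] <= peaks[1][0]


class TestPoissonPvalue:
    def test_k_zero_is_one(self):
        assert poisson_pvalue(0, 3.7) == 1.0

    def test_matches_brute_force_series_oracle(self):
        # independent oracle: direct summation of the Poisson upper tail
        def series(k, lam):
            total, term = 0.0, math.exp(-lam)
            for i in range(0, k + 200):  # tail beyond k+200 is negligible here
                if i >= k:
                    total += term
                term *= lam / (i + 1)
            return total

        for lam in (0.1, 1.0, 5.0, 20.0):
            for k in range(0, 51):
                assert poisson_pvalue(k, lam) == pytest.approx(
                    series(k, lam), abs=1e-10
                )

    def test_monotone_decreasing_in_k(self):
        values = [poisson_pvalue(k, 4.2) for k in range(30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            poisson_pvalue(3, 0.0)
        with pytest.raises(ValueError):
            poisson_pvalue(-1, 1.0)


def _profile_with_nucleosome(chrom_len=4000, edge5=1000, edge3=1150, n_each=20):
    reads = [Read("c", edge5 - 1, edge5 + 24, "+") for _ in range(n_each)]
    reads += [Read("c", edge3 - 24, edge3 + 1, "-") for _ in range(n_each)]
    return extend_and_pile(reads, {"c": chrom_len})["c"]


class TestScoreAndQc:
    def test_canonical_interval_is_147_centered_on_midpoint(self):
        profile = _profile_with_nucleosome()
        [peak] = score_candidates(profile, [(1000, 1151)], 4000)
        mid = (1000 + 1151) // 2
        assert peak.canonical.start == mid - 73
        assert peak.canonical.end == mid + 74
        assert peak.canonical.width == 147

    def test_strand_counts_and_ratio(self):
        profile = _profile_with_nucleosome(n_each=12)
        [peak] = score_candidates(profile, [(1000, 1151)], 4000)
        assert peak.n_plus == 12 and peak.n_minus == 12
        assert peak.strand_ratio == 1.0
        assert peak.read_count == 24

    def _fabricate(self, width=150, n_plus=9, n_minus=3, chrom_len=100_000):
        edge5, edge3 = 1000, 1000 + width
        reads = [Read("c", edge5 - 1, edge5 + 24, "+")] * n_plus
        reads += [Read("c", edge3 - 24, edge3 + 1, "-")] * n_minus
        profile = extend_and_pile(reads, {"c": chrom_len})["c"]
        return score_candidates(profile, [(edge5, edge3)], chrom_len)

    @pytest.mark.parametrize("width,kept", [(79, False), (80, True), (250, True), (251, False)])
    def test_width_boundaries(self, width, kept):
        candidates = self._fabricate(width=width, n_plus=20, n_minus=20)
        assert bool(qc_filter(candidates)) is kept

    @pytest.mark.parametrize("n_plus,kept", [(9, True), (10, False)])
    def test_strand_ratio_boundary_at_three(self, n_plus, kept):
        # 9/3 = 3 passes; 10/3 > 3 fails
        candidates = self._fabricate(n_plus=n_plus * 4, n_minus=12)
        assert bool(qc_filter(candidates)) is kept

    def test_one_empty_strand_fails_the_ratio_filter(self):
        candidates = self._fabricate(n_plus=40, n_minus=0)
        assert math.isinf(candidates[0].strand_ratio)
        assert qc_filter(candidates) == []

    def test_insignificant_poisson_p_is_removed(self):
        candidates = self._fabricate(n_plus=20, n_minus=20)
        assert qc_filter(candidates, alpha=1e-5)  # clearly enriched
        assert qc_filter(candidates, alpha=candidates[0].poisson_p / 10) == []

    def test_overlapping_canonicals_keep_lower_p(self):
        profile = _profile_with_nucleosome(n_each=30)
        weak = _profile_with_nucleosome(n_each=10)
        strong = score_candidates(profile, [(1000, 1151)], 4000)
        shifted = score_candidates(weak, [(1040, 1191)], 4000)
        kept = qc_filter(strong + shifted)
        assert len(kept) == 1
        assert kept[0].read_count == 60


def test_caller_recovers_planted_nucleosomes_small(small_config, small_dataset):
    from nucleoclass.preprocess import deduplicate, normalize_depth

    unique = {
        mark: deduplicate(reads, mark)[0]
        for mark, reads in small_dataset.outcome_reads.items()
    }
    normalized = normalize_depth(unique, seed=small_config.seed)
    for mark, reads in normalized.items():
        peaks = call_nucleosomes(reads, small_config.chrom_lengths)
        assert midpoint_recovery_rate(small_dataset.truth, peaks, mark) >= 0.9
        assert all(pk.canonical.width == 147 for pk in peaks)


def test_caller_supports_gaussian_denoise_backend(small_config, small_dataset):
    from nucleoclass.preprocess import deduplicate

    mark = small_config.pos_mark
    reads = deduplicate(small_dataset.outcome_reads[mark], mark)[0]
    peaks = call_nucleosomes(
        reads, small_config.chrom_lengths, denoise_method="gaussian"
    )
    assert midpoint_recovery_rate(small_dataset.truth, peaks, mark) >= 0.9
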