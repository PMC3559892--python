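# Methods

## Problem and model

Two chromatin marks that cannot co-occur on one nucleosome — a symmetric
histone arginine dimethylation (the *positive* mark) and the histone
variant H2A.Z (the *negative* mark) — leave distinguishable ChIP-Seq
signatures. The package treats discrimination as a supervised binary
classification over *stable nucleosomes*: positions where reads pile up
because the nucleosome sits at nearly the same coordinate across the cell
population. All coordinates are 0-based half-open throughout; any 1-based
display would belong to a reporting layer only.

## Pre-processing

Duplicates are collapsed on the `(chrom, start, strand)` key. With
fixed-length single-end reads the 5' end identifies the sequenced fragment,
so this is equivalent to keying on the full interval; it is the standard
PCR-duplicate criterion and the one we adopt since the alternative is
unobservable with this data type. Depth normalization down-samples every
deduplicated sample, uniformly without replacement and seeded, to the
minimum unique-read count across samples; the minimal sample passes through
untouched. Dedup-then-normalize is the only supported order.

## Stable-nucleosome calling

Reads are extended 150 bp in their 3' direction (the MNase mononucleosomal
fragment length) and piled into per-bp coverage. The profile is denoised
by stationary-wavelet soft shrinkage (`sym4`, 4 levels, universal threshold
with the noise scale estimated from the finest detail band by MAD; a zero
threshold short-circuits to the identity, which keeps noise-free profiles
exact). A Gaussian-kernel smoother (σ = 15 bp) is available as an
alternative backend; both backends must pass the same peak-recovery
contract. Peak edges are the boundaries of maximal negative runs of the
Laplacian-of-Gaussian filtered profile (σ = 25 bp) — the concave region
between the two zero crossings flanking each signal maximum — so peaks are
disjoint by construction.

Each candidate peak of width *w* collects the reads whose extended interval
overlaps its raw edges, per strand. The background expectation is the
per-chromosome uniform-placement rate, λ = n·(w + 149)/L for n reads on a
chromosome of length L: the datasets of interest have no mock-IP control,
so uniform background is the null (a documented assumption). The retained
peaks satisfy 80 ≤ w ≤ 250 bp, strand ratio ≤ 3 (an empty strand counts as
infinite and fails), and Poisson upper tail P(X ≥ k) ≤ 10⁻⁵, computed via
the survival function; p-values are reported unadjusted — the threshold
acts per peak, not as an FDR. Read counts use raw (not denoised) signal
within the raw edges; the denoised profile only locates edges.

Canonical intervals are [mid − 73, mid + 74) with mid = ⌊(start + end)/2⌋:
147 is odd, and the extra bp goes right so outputs are reproducible
bit-for-bit. If two canonical intervals from one sample overlap, the
lower-p peak wins — stable nucleosomes are non-overlapping by definition.

## Modification features

Each stable nucleosome receives one integer per feature channel: the
number of deduplicated feature reads whose 5' end falls in the closed
101-bp window around the matching boundary ('+' reads at the canonical
start, '−' reads at the canonical end − 1). "Within ±50 bp" is read as
closed bounds on the 5'-end coordinate — the mapped position of a ChIP tag
— which makes the strand-specific phrasing exact. Counts are used rather
than binary stable-nucleosome overlap because they give a denser matrix.
Feature reads are deduplicated but not depth-normalized by default; since
the normalization status of this step is genuinely ambiguous, the caller
can supply normalized reads instead and nothing else changes.

## Sequence features (discriminatory motif selection)

Sequences (the canonical 147 bp intervals, forward strand) are split
stratified into a discovery fraction f = 0.2 and a classification
remainder, seeded; the two partitions are disjoint by id and feeding a
discovery sequence into the feature matrix raises a hard error.

On the discovery set, every k-mer (5 ≤ k ≤ 10) observed in the data is a
candidate; a k-mer and its reverse complement are one candidate (presence
counted once per sequence regardless of strand or multiplicity — a
deliberate resolution of the palindrome double-counting question).
Candidates must appear in ≥ 5% of one class's discovery sequences (a
singleton-noise floor; the underlying engine this stage replaces does not
document one). Scoring is the pooled two-proportion z-statistic on
presence; presence stabilizes the statistic on 147 bp sequences, while the
downstream matrix uses counts, which preserve the abundance signal.
Ranking is by |z|, ties broken by length (longer first — at equal
discrimination a longer motif is more specific, which is the very reason
for allowing lengths beyond 6), then favored-class abundance, then
lexicographic order; raw abundance makes a poor first tie-break because on
tandem-repeat sequences it is decided by ±1 edge-window counts. A
candidate that is a substring (either orientation) of a retained
higher-ranked candidate is redundant and dropped. At most 300 motifs are
returned.

Matching on the classification set counts all windows, forward strand plus
reverse complement, within Hamming distance M = 2 of the motif. M is
global, not length-scaled; a warning is logged when 5-mers are elicited,
since at M = 2 they match a large fraction of random windows.

## Classification and importance

The larger class is down-sampled without replacement to the smaller's size
(seeded), ten times; each balanced matrix is fit with a 500-tree random
forest, m_try = ⌊√p⌋ (floor is the conventional integerization of √p).
Accuracy and auROC are out-of-bag: each sample is scored by the vote
fraction of trees whose bootstrap excluded it; rows never OOB (possible
with small forests) are excluded from the estimate. Reported spread across
the ten repeats is the standard deviation, labeled as such. ROC ties in
vote fraction are handled by trapezoidal interpolation.

MDG is the unnormalized per-tree Gini-impurity decrease summed over a
feature's splits (node-fraction weighted), averaged over trees and then
over repeats. Each feature's direction annotation is the class with the
higher mean feature value.

Significance: class labels are permuted B times and the forest refit; the
add-one estimator p = (1 + #{permuted MDG ≥ observed MDG})/(1 + B) never
returns zero and is conservative; Bonferroni multiplies by the feature
count, capped at 1. B defaults to 1000 with a reduced 100-tree refit per
permutation — a deliberate desk-scale deviation from exhaustive
permutation; both knobs are configurable. The observed MDG inside the test
is recomputed with the same reduced forest, because exchangeability
between the observed statistic and the null draws is what keeps the
p-values calibrated (verified by a null-calibration test); the headline
MDG ranking still comes from the full 500-tree evaluation. With B = 1000
the smallest attainable p is 1/1001 ≈ 10⁻³, hence the smallest attainable
Bonferroni-adjusted p over 37 features is ≈ 0.037.

## Satellite analysis

Composition: per mark, bound DNA is the *union* of canonical intervals (a
set of bp, never a multiset), intersected with the union of each repeat
family's annotation intervals; the families used are satellite II
(`HSATII`) and satellite III (`(CATTC)n`, `(GAATG)n`), which are disjoint
in our annotations so fractions sum to ≤ 1.

Occupancy: repeat instances are aligned at their genomic start
(annotations are strandless), and occupancy at offset t is the fraction of
instances covered there by ≥ 1 canonical nucleosome of the mark, among
instances longer than t. The scalar summary is the mean occupancy over
offsets up to the median instance length; no standard reduction exists for
this statistic, so the full profile is always emitted and any other
reduction can be recomputed from it.

Motif histograms count exact forward-strand overlapping occurrences in the
extracted nucleosome sequence; whether both strands should be counted is
ambiguous, and forward-only is the documented choice.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Genome** — i.i.d. uniform ACGT background, default 200 kb on one
  chromosome, overwritten by satellite arrays: satellite II units are two
  copies of `ATTCCATTCG` plus 1–2 copies of `ATG`; satellite III units are
  7–13 copies of `ATTCC` plus one `ATTCGGGTTG`. Units are emitted
  uppercase (case in published consensus tables encodes conservation, not
  sequence). Defaults: 5 arrays of each type, 60–90 (satellite II) and
  35–55 (satellite III) units per array.
* **Nucleosomes** — 50 positive-class nucleosomes in slots inside satellite
  arrays spaced ≥ 150 bp apart, 50 negative-class nucleosomes in background
  at least 200 bp from anything else, all exactly 147 bp. Both classes are
  planted with the same read-count distribution so classes differ only in
  sequence context and feature co-localization, never in coverage depth.
* **Reads** — 25 bp; per nucleosome, Poisson(reads_per_nuc/2) '+' reads
  with 5' ends Normal(5'-edge − 1, σ = 5 bp) and the mirrored count of '−'
  reads at the 3' edge, so 3'-extension stacks them over the nucleosome —
  the geometry the caller assumes. Uniform background at 0.001 reads/bp;
  each emitted read is duplicated with probability 0.06 (giving a ≈ 5.7%
  duplicate fraction, the middle of the realistic range; rates up to ≈ 0.34
  reproduce the ≈ 25% upper end). Per-sample depth multipliers emulate
  depth variation. 40 reads per planted nucleosome by default.
* **Feature channels** — 37 named channels (19 methylations + 18
  acetylations); channels in the co-localization map (default: H4K20me3 at
  intensity 10 and H3K9me3 at 6, both on the positive class) emit signal
  reads at their mapped class's nucleosomes, all others background only.
* **Determinism** — one seed fixes every output bit-identically; internal
  streams are keyed by CRC32 of their purpose so adding a channel never
  perturbs the others.

What the generator does **not** emulate: mappability and GC bias,
chromatin-state structure beyond the planted classes, fragment-length
variation, fuzzy (delocalized) nucleosomes, biological duplicate reads,
and any non-uniform background (the real datasets lack a mock IP, so no
background model can be fit from them). Passing tests therefore
demonstrate correctness of the algorithms under the stated read model, not
performance on real tissue data; on real data the classes are far larger
(thousands of nucleosomes) and noisier, and genome-scale inputs are
accepted through the same BED/FASTA interfaces.

## Problem sizes and numerics

Tests and the reproduction script run the default 200 kb / 50+50-nucleosome
study — chosen so the complete analysis, including the 1000-permutation
importance test, completes in minutes while every statistical property
(recovery, calibration, separation) is measurable. Float accumulations
make quantities like a mean of ten identical accuracies differ from the
exact value by ~10⁻¹⁶; cross-platform reproducibility of reported numbers
is expected at ~10⁻¹² while outputs on one platform are bit-stable.
Degenerate inputs fail loudly: empty samples, constant labels, classes
with fewer than two sequences, λ ≤ 0, empty repeat-instance sets and
out-of-bounds intervals all raise errors rather than guessing.

## Known limitations

* The motif elicitor is a transparent z-statistic engine behind the same
  contract as specialized word-discovery tools; it cannot find gapped or
  probabilistic (PWM) motifs and may miss features whose effect is a pure
  interaction.
* The Poisson background is uniform per chromosome; enrichment against a
  structured background (e.g. open chromatin) will be overstated.
* Occupancy summaries depend on the chosen reduction (mean to the median
  instance length); the per-offset profile is the primitive quantity.
* Multi-class discrimination (one-against-all over many marks) is out of
  scope, as are SVM comparators and single-tree rule extraction.
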