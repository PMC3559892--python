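# nucleoclass

Discriminating stable nucleosomes that carry two mutually exclusive
chromatin marks — a histone arginine methylation (H2A/H4R3me2s) versus the
histone variant H2A.Z — from aligned ChIP-Seq reads.

ChIP-Seq for histone modifications is mostly background: only a minority of
reads derive from nucleosomes actually bearing the immunoprecipitated mark.
This package implements the full analysis chain needed to classify marks
accurately anyway, for epigenomics analysts working with BED-format read
data:

1. **Pre-processing** — collapse PCR duplicates (one read per
   `(chrom, start, strand)` key) and down-sample every sample to the lowest
   unique-read count, removing amplification and depth bias.
2. **Stable-nucleosome calling** — extend reads 3' to 150 bp (the
   mononucleosomal fragment length), pile up coverage, denoise
   (stationary-wavelet shrinkage or Gaussian smoothing), detect peak edges
   with a Laplacian-of-Gaussian filter, and keep peaks with width
   80 ≤ *w* ≤ 250 bp, strand ratio *s* = max(n₊, n₋)/min(n₊, n₋) ≤ 3, and
   Poisson upper-tail *p* ≤ 10⁻⁵ against a uniform background; each peak is
   reported as its canonical 147 bp midpoint-centered interval.
3. **Histone-modification features** — for each stable nucleosome, a
   37-entry array counting deduplicated feature-mark reads whose 5' ends
   fall within ±50 bp of the matching nucleosome boundary ('+' reads at the
   5' boundary, '−' reads at the 3' boundary).
4. **DNA-sequence features** — discriminatory motif feature selection:
   elicit ≤ 300 motifs of length 5–10 on a withheld discovery partition
   (fraction *f* = 0.2), scored by a two-proportion z-statistic on
   per-sequence presence (both strands), then build mismatch-tolerant
   (≤ *M* = 2) match-count features on the disjoint classification
   partition. A leakage guard makes discovery/classification reuse a hard
   error.
5. **Classification** — balanced random forests (*n*₍tree₎ = 500,
   *m*₍try₎ = ⌊√p⌋, ten balanced down-samplings of the larger class),
   evaluated out-of-bag (accuracy and auROC from OOB vote fractions);
   feature importance by mean decrease in Gini index (MDG) with an add-one
   permutation test and Bonferroni adjustment.
6. **Satellite-repeat analysis** — composition of nucleosome-bound bp by
   repeat family (satellite II = `HSATII`; satellite III = `(CATTC)n`,
   `(GAATG)n`) and occupancy profiles over start-aligned repeat instances.

A seeded synthetic-data generator (`nucleoclass.synthetic_data`) builds toy
genomes with satellite II/III consensus arrays, planted 147 bp nucleosomes,
strand-structured read pileups, PCR duplicates and co-localized feature
channels, so the entire pipeline is testable without external downloads.
Real BED/FASTA inputs are supported through the same interfaces.

## Worked example

```python
from nucleoclass import SyntheticConfig, run_pipeline

results = run_pipeline(SyntheticConfig(seed=1), outdir="out")
mod = results["modification_classification"]
sat = results["satellite_analysis"]
print(f"accuracy {mod['accuracy_mean']:.3f} +/- {mod['accuracy_sd']:.3f}, "
      f"auROC {mod['auroc_mean']:.3f}, top feature {mod['top_feature']}")
print("satellite fraction of bound DNA:",
      {m: round(sum(v for k, v in c.items() if k != 'residual'), 3)
       for m, c in sat["composition"].items()})
print("TCCATT prevalence:", sat["tccatt_prevalence"])
```

prints

```
accuracy 0.990 +/- 0.000, auROC 1.000, top feature H4K20me3
satellite fraction of bound DNA: {'H2AZ': 0.0, 'H4R3me2s': 1.0}
TCCATT prevalence: {'H2AZ': 0.0, 'H4R3me2s': 1.0}
```

Read it as: with two feature channels (H4K20me3, H3K9me3) co-localized with
the positive mark, the balanced forest separates the two nucleosome classes
at 99% OOB accuracy and ranks the planted channel first by MDG; all of the
positive mark's bound DNA lies in satellite arrays (none of the negative
mark's does), and every positive-mark nucleosome sequence contains the
satellite consensus 6-mer TCCATT while no negative-mark sequence does.
`out/` additionally receives the peak BEDs, feature matrices, motif table,
importance table with permutation p-values, and occupancy profiles.

The same stages are scriptable from the shell:

```sh
nucleoclass simulate --seed 1 --outdir data
nucleoclass preprocess --in data/H4R3me2s.bed --in data/H2AZ.bed \
    --seed 1 --outdir pre
nucleoclass call --in pre/H4R3me2s.bed --genome-sizes sizes.tsv \
    --out peaks_pos.bed
nucleoclass run --seed 1 --outdir out     # everything end to end
```

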