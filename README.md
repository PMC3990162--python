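# cnaprog

Copy-number-alteration (CNA) progression analysis for sequential lesion
aCGH profiles: segmentation of probe-level log2-ratio data, gain/loss
calling, population-CNV filtering, progressive-vs-non-progressive
subtraction, recurrent-region construction with sequential-recurrence
classification, hierarchical profile clustering, and the validation-arm
statistics (ΔΔCt relative quantification, Kruskal–Wallis, Fisher's exact).

A first-class synthetic-cohort generator produces desk-scale cohorts with
implanted truth sets (shared progression-core alterations, grade-acquired
alterations with monotone presence, germline population CNVs, private
events) so every stage of the pipeline can be tested against known ground
truth.

## Layout

| Module | Role |
| --- | --- |
| `cnaprog.core_io` | Domain types, interval arithmetic, readers/writers (probe TSV, sample sheet CSV, calls BED5+, CNV catalog BED4+, cytobands) |
| `cnaprog.synthetic_data` | Seeded cohort simulator with truth sets and plain-text fixture round-trip |
| `cnaprog.segmentation` | Recursive Welch-t change-point segmentation, SNR merge pass, gain/loss calling, profile concordance |
| `cnaprog.progression_filter` | Population-CNV filter, group subtraction, recurrent regions, sequential-recurrence classes, frequency tables |
| `cnaprog.clustering` | Binned feature matrices, average-linkage Euclidean clustering, adjusted-Rand separation score |
| `cnaprog.validation_stats` | ΔΔCt fold quantities, tie-corrected Kruskal–Wallis, two-sided Fisher's exact (point-probability method) |

Coordinates are 0-based half-open (BED convention); only autosomes
`chr1`..`chr22` are admitted — sex-chromosome rows are dropped at ingest.
Calls compare `2**mean_log2` to linear-ratio thresholds 1.15 (gain) and
0.85 (loss); segmentation defaults are 10 minimum markers, split p < 0.001
and a signal-to-noise cut-off of 0.3.

## CLI

```sh
# generate a seeded synthetic cohort fixture
cnaprog simulate --seed 1 -o cohort/

# segment one sample's probes into calls
cnaprog segment cohort/P1L1.probes.tsv -o P1L1.bed

# population-CNV filter + non-progressive subtraction
cnaprog filter --catalog cohort/catalog.bed prog.bed nonprog.bed -o filtered.bed

# recurrent regions with sequential-recurrence classes; frequency table
cnaprog recur --sheet cohort/samples.csv filtered.bed -o regions.tsv
cnaprog freqtable --sheet cohort/samples.csv filtered.bed -o freq.tsv

# hierarchical clustering of profiles (Newick + separation report)
cnaprog cluster --sheet cohort/samples.csv -o clust cohort/*.probes.tsv

# concordance between two profiles on one probe grid
cnaprog concordance a.probes.tsv b.probes.tsv

# qPCR fold table and a 2x2 Fisher test
cnaprog qpcr --calibrator normal1 ct.csv -o folds.tsv
cnaprog assoc 17 2 5 8
```

`simulate` and `segment` accept YAML config files overriding the
`CohortConfig` / `SegmentationParams` defaults.

## Notes

- The synthetic noise default (`noise_sd = 0.1` on the log2 scale) is a
  modeling choice, not a measured value; implanted effect sizes default to
  single-copy algebra (gain `log2(3/2)`, loss `log2(1/2)`).
- The two-sided Fisher p uses the point-probability convention (sum of
  margin-consistent tables as or less probable than the observed one).
- No multiple-testing correction is applied across genes in the qPCR arm;
  significance is raw p < 0.05 by design.
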