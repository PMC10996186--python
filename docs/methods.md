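# Methods

## Data model and filtering

CpG calls are per-dyad records `(chrom, pos, n_meth, n_unmeth)` with `pos`
the 1-based coordinate of the plus-strand C. Input coverage files
(6-column, 1-based inclusive, tab-delimited, optionally gzipped) are
parsed strictly; the percent column is never trusted and levels are always
recomputed from counts, which makes the pipeline robust to the rounding
dialects of different methylation extractors. Plus/minus strand records of
one dyad are summed onto the plus-strand coordinate by default (per-strand
analysis remains possible by skipping the merge); strand merging and
replicate pooling commute because both are count additions.

The coverage filter keeps sites with 3–100 reads, both bounds inclusive —
the conventional closed reading of a dash range; the lower bound removes
unreliable shallow sites, the upper bound collapsed-repeat pileups.
Replicates are pooled by summing counts per site (not averaging levels),
and the coverage filter is re-applied afterwards because pooling changes
depths. The unmethylated spike-in contig (lambda-phage-sized, 48.5 kb)
estimates bisulfite conversion as `1 − Σm/Σ(m+u)` over its sites; the rate
is reported but never used to exclude a library.

## Regional methylation

All regional levels are weighted (read-count) levels, not means of site
fractions: depth-robust, and exactly consistent under aggregation — the
concatenation of all grid windows reproduces the global level to machine
precision, and any interval level equals the count-pooling of its sites.
The grid is anchored at 0, half-open, 10 kb by default; the last partial
window of a chromosome is kept if it passes the 5-informative-CpG minimum.
"Informative" means passing the 3–100 filter. Sex chromosomes would be
included; the spike-in contig is always excluded from genomic summaries.
Cross-sample comparisons use the intersection of informative windows,
taken after replicate pooling.

## DMR calling

A window enters the tested universe when informative (≥ 5 CpGs) in both
samples and sharing ≥ 2 informative sites. Δ is the difference of the two
windows' weighted levels × 100. The test is a two-sided Welch t across the
per-site methylation fractions of shared sites. Sites are the replication
unit because replicates are pooled upstream; testing across replicates or
read-level calls would be alternatives, and the site-level choice is the
one that remains well-defined after pooling. Degenerate windows with zero
variance in both samples get p = 1 at equal means and p = 0 otherwise.
Calls require strict `|Δ| > 10` and `p < 0.05` with no multiple-testing
correction. Under an identical-truth null (10,000 windows, depth 20,
beta-binomial overdispersion 0.05) the observed p < 0.05 rate is
0.048–0.053 across seeds, so the site-level Welch approximation is
well calibrated at these depths.

## Annotation characterization

Genomic context assigns each base one category with precedence
repeat class (LTR / LINE / SINE / satellite / other) > exon > intron >
intergenic; proportions are base-pair fractions over the region set and
sum to 1, and fold enrichment divides by the same category's whole-genome
share. Repeat families aggregate counts over all copies of a family (name
match, either strand; overlapping copies of one family are merged so no
site is double-counted); only families with ≥ 50 annotated copies are
summarized. ICR records report weighted levels per named interval and the
KO/control ratio; the fold is undefined (not infinite) at control level 0
and flagged above 1.3.

## Chromatin association

Per-window mark enrichment is
`log2((ip_w/IP_total + ε) / (input_w/Input_total + ε))` with ε the
pseudocount rescaled into proportion units (averaged over the two library
sizes), so proportional libraries score exactly 0 and zero-count windows
stay finite. Top-quantile selection takes the `⌈qN⌉` highest-scoring
windows with ties broken by genomic order for determinism, which makes
nested quantiles strictly nested. Only relative comparisons of scores
(set A vs set B medians/quartiles) are treated as meaningful; absolute
scores depend on the enriched fraction through library-size normalization.

## Fate classification

Stages are compared by fixed-grid window identity — never by interval
overlap fraction — so persistence is exact set algebra. Each flagged
window gets one category (`persistent_to_FGO`, `PGC_only`, `FGO_only`,
`E11.5_and_FGO`, `lost_after_E11.5`); the categories partition the union
of all stage sets. Every derived percentage is stored with its explicit
numerator, denominator and exact value; rounding to whole percent happens
only at display.

## Differential expression

Genes pass when (1) mean FPKM ≥ 1 in either group, (2) fold change > 4 on
group means with a 0.1-FPKM pseudocount (avoids division by zero; the
choice of raw-mean folds with a small pseudocount is a design decision —
log-scale folds would differ only for highly dispersed replicates), and
(3) two-sided Welch t on log2(FPKM + 0.1) gives p < 0.05. Small annotated
RNAs are expected to be excluded upstream of the matrix.

## Synthetic data generator

The generator is the package's validation instrument: it emulates the
statistical structure the analysis assumes and exposes the planted truth.

* **Genome**: four 5-Mb chromosomes plus a 48.5-kb unmethylated spike-in;
  CpG dyads at ~1/100 bp with uniform jitter (~200k dyads, 2,000 grid
  windows).
* **Annotations**: an IAP-like LTR family (200 × 2 kb), a LINE-like family
  (250 × 3 kb), a SINE-like family (400 × 150 bp), a clustered satellite
  block (80 × 1 kb), a second LTR family, one deliberately sub-50-copy
  family (to exercise the copy-number rule), 60 genes with exons, and 15
  ICRs.
* **Stage trajectory** (control weighted level): epiblast 0.70, E9.5 0.30,
  E10.5 0.15, E11.5 0.091, E13.5 0.030, E16.5 0.022, GO 0.15, FGO 0.40.
  The PGC values anchor the near-complete erasure window; the FGO value
  the oocyte's de novo methylation. E13.5 sits between the E11.5 and
  E16.5 anchors to keep the erasure monotone; the GO value reflects early
  de novo methylation.
* **KO effect**: every H3K9me3-marked window (windows overlapping IAP-like
  or satellite copies) is planted with +0.30 at E11.5 and carries a fate
  category drawn 40% lost / 25% PGC-only / 35% persistent, which sets its
  delta schedule at later stages (+0.25 at E13.5/E16.5 where retained,
  +0.30 in FGO for the persistent class); 100 unmarked windows are planted
  +0.35 in FGO only. Sites inside IAP-like copies get an extra +0.10
  following the same schedule, making that family the single most
  hypermethylated repeat family ahead of the satellite. Five of the 15
  ICRs retain methylation in the KO (0.30 vs the 0.10 erasure remnant) at
  PGC stages.
* **Noise model**: depth ~ Poisson(15) clamped to ≥ 1; site-level
  methylation ~ Beta with mean at the (conversion-adjusted) truth and
  overdispersion ρ = 0.05; reads ~ Binomial. Conversion failures inflate
  apparent methylation as `p_obs = p + (1−p)·e` with e = 0.005, and the
  spike-in truth is 0, so the measured conversion rate is ~0.995. A
  `noiseless` mode replaces sampling with deterministic rounding at fixed
  depth for oracle runs. Two replicates per sample by default.
* **Seeding**: every sampling task derives an independent stream from the
  master seed via a stable label hash, so outputs are byte-identical under
  one seed and adding a sample never perturbs another.

What the generator does **not** emulate: real genome sequence and CpG
density heterogeneity (islands, shores), mappability and coverage biases,
chromosome-scale methylation domains, subfamily age structure within
repeat families, allele-specific ICR methylation, and 5hmC. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the planted model, not performance on real mouse data, where effect
sizes are smaller and noise is structured.

## Problem sizes and numerical choices

Default test/analysis scale (~200k CpGs, 2,000 windows, 16 libraries) was
chosen so a full pipeline run completes in seconds and the complete
validation (including a 10,000-window null calibration and a ~500-window
recall simulation at depth 20) in about a minute on one CPU. Genome-scale
counts from real data (tens of thousands of DMRs) are not reproducible at
this scale; the count/percentage *arithmetic* of the summary and fate
stages is instead verified exactly on constructed window sets of realistic
sizes. Ties: |Δ| exactly at the threshold is never a DMR (strict
inequality); quantile ties resolve by genomic order; equal-mean
zero-variance windows get p = 1. All percentages are exact fractions until
display.

## Known limitations

The site-level t-test treats neighbouring CpGs as independent; spatial
correlation within windows in real data makes the test anti-conservative
there, which is one reason the strict effect-size threshold accompanies
the p-value. No smoothing or imputation is attempted for low-coverage
windows — they simply leave the universe, so DMR counts depend on depth
through window informativeness. ICR folds are undefined at fully erased
control ICRs. The expression filter requires ≥ 2 replicates per group and
is a filter, not a shrinkage-based DE model.
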