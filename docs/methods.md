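# Methods

## The analysis model

The pipeline is a deterministic, threshold-based characterisation of
differential DNA methylation between two groups of RRBS libraries. It
assumes per-CpG methylated/unmethylated read counts as produced by the
Bismark coverage extractor (1-based positions, counts per cytosine) and
makes three substantive choices:

1. **Joint scoreability.** A CpG enters the analysis only if it is observed
   with coverage strictly greater than 8 reads in *every* sample. The strict
   reading of "> 8" (coverage ≥ 9) is the default; the bound is the
   `min_cov_exclusive` parameter, so the inclusive interpretation is one
   flag away. Intersection precedes the coverage test: "in every sample" is
   undefined for a locus a library never saw, and RRBS libraries routinely
   miss each other's fragments.
2. **Single-linkage regions.** Scoreable CpGs at most `max_gap` = 50 bp
   apart chain into one region. Chaining is transitive, so a dense cluster
   can form a region far wider than 50 bp; any non-transitive rule would
   need an arbitrary tie-break. Singleton regions are kept (`--min-cpgs`
   can drop them); region identity is `chrom:start-end` over member
   cytosine positions.
3. **Effect-size DMR call.** Group methylation of a region is the
   coverage-weighted pooled percentage (sum counts over member CpGs and
   group samples, then divide); this uses every read and is well defined
   with a single library per condition, which is the design this analysis
   was built for. An unweighted per-CpG mean is available
   (`aggregation="mean"`) for sensitivity analysis. With
   Δ = treatment − control in percentage points, |Δ| must *strictly* exceed
   `delta_threshold` = 5 to be called; exactly ±5.0 is unchanged. "5%" is
   five percentage points of absolute methylation, not a relative change.
   No p-value or multiple-testing correction is computed — the method is a
   pure effect-size rule, and its false-call behaviour is quantified by
   simulation instead (below).

Delta's sign convention makes the control group the reference, so in a
re-expression experiment "methylation lost upon re-expression" is Δ < −5.
Swapping the groups negates every Δ exactly and exchanges the
increased/decreased totals (this antisymmetry is asserted in the tests).

## Genomic-context annotation

Annotation reimplements peak-annotation practice (first-match priority) at
the granularity of five labels: **TSS** (region overlaps TSS ± 100 bp),
**promoter** (the strand-aware upstream band from 2,000 bp to 101 bp before
the TSS), **exon**, **intron** (inside a transcript span but touching no
exon), **intergenic** (catch-all). Exact window sizes used by annotation
tools vary between versions and are not standardised; both windows are
parameters (`tss_window`, `promoter_window`). The TSS is the 5′ span end per
strand; BED12 input is converted to 1-based inclusive coordinates at the
boundary and chromosome names are compared as exact strings, because silent
"chr1" vs "1" mismatches are the most common failure mode of this kind of
analysis.

Distance to the nearest TSS is measured from the region midpoint
(⌊(start+end)/2⌋), signed negative upstream in the gene's orientation; ties
in absolute distance break toward the lower-coordinate TSS, then the
lexicographically smaller gene id. Summaries (quartiles per direction) use
absolute kb, matching how such distributions are usually displayed. A region
on a chromosome with no annotated gene gets no distance (and is excluded
from distance summaries) rather than a meaningless cross-chromosome number.

Conservation between two comparisons counts a direction-matched query DMR as
conserved when it overlaps a same-direction reference DMR by ≥ 1 bp. Since
no convention fixes the denominator, the fraction is reported in both
orientations plus a base-pair Jaccard (intersection bp / union bp of the two
merged region sets — the bedtools-jaccard convention, cross-checked against
bedtools in the test suite). A minimum reciprocal-overlap option exists but
defaults to 0 (any overlap).

## The synthetic methylome generator

The generator produces Bismark-format fixtures with the statistical
structure the analysis assumes, plus a ground-truth table. What it emulates,
per component, with defaults chosen to be realistic for RRBS at desk scale:

* **CpG positions** — a two-scale gap mixture: with probability
  `p_cluster` = 0.85 a short within-cluster gap (geometric, mean 12 bp,
  minimum 2 bp), otherwise a long between-cluster gap (geometric, mean
  2,600 bp). The mean gap is ≈ 400 bp, giving ≈ 50,000 CpGs on the default
  2 × 10 Mb genome, organised in dense clusters like MspI fragments.
* **Coverage** — negative binomial per CpG per sample (mean 50, size 5;
  CV ≈ 0.5, typical of RRBS library depth variation), truncated at ≥ 1 by
  omission: a zero-coverage CpG is absent from that sample's table, exactly
  as Bismark omits unobserved cytosines. This exercises the intersection
  logic with realistic locus dropout.
* **Methylation** — each realized CpG cluster (the ≤ 50 bp chain) draws one
  baseline level μ from Beta(0.4, 0.4), the bimodal shape of genome-wide
  CpG methylation. Counts are beta-binomial: per CpG per sample,
  p ~ Beta(μc, (1−μ)c) with concentration c = `meth_precision` = 300
  (dispersion ≈ 0.003, appropriate for isogenic cell-line libraries), then
  methylated reads ~ Binomial(coverage, p). `meth_precision=None` gives the
  pure binomial mode used for analytic convergence checks, where measured
  region deltas must approach the planted truth as coverage grows.
* **Planted DMRs** — 200 clusters of 8–40 CpGs are selected among clusters
  whose baseline permits the full ±25-point shift (μ + Δ within
  [0.01, 0.99]); the treatment-group μ is shifted and clamped, and the
  achieved shift is recorded in the truth table (clamping can only occur in
  user configs that force it, and then triggers a warning). Selecting
  shift-compatible clusters, rather than re-drawing baselines, keeps the
  background beta distribution intact while making the planted truth exact.
  Half the planted regions are decreases (`planted_frac_decreased`).
  Because planting operates on realized clusters — which are separated by
  more than 50 bp by construction — each truth region maps to one assembled
  region and recovery is well defined without fuzzy matching.
* **Genes** — non-overlapping 5–20 kb models with random strand and 2–8
  exons, packed into per-gene slots (120 genes by default). The
  `simulate_tss_scenario` helper packs all genes into the first 4 Mb of each
  chromosome and plants decreases ≥ 50 kb from every TSS and increases
  within 2 kb, at high coverage in binomial mode, so the recovered
  distance/context contrast between directions is attributable to placement
  rather than noise.

One library per group is the default (`group_sizes=(1, 1)`), matching the
single-library-per-condition contrasts this analysis was designed around.
Everything is deterministic given the seed.

**Error budget for the defaults.** The sampling variance of a region's
measured Δ with k member CpGs at coverage n per sample is approximately
2·μ(1−μ)·(1/(kn) + 1/((c+1)k)) — a read-sampling term and a replicate
overdispersion term. At n = 50, c = 300 and planted widths of 8–40 CpGs,
the per-region standard deviation is ≈ 1.5–4 points depending on μ and k,
giving an expected recovery RMSE of ≈ 2.5 points against ±25-point planted
shifts and essentially certain detection — which is what the acceptance
checks measure. The same arithmetic explains the null behaviour: small
regions at low coverage carry per-region noise of 7–15 points, so a pure
> 5-point rule inevitably calls many of them, and the false-call rate falls
monotonically as coverage grows (binomial term shrinks) while deeply pooled
regions (≥ 1,000 reads per group) are called rarely.

## What passing tests do and do not show

The generator reproduces clustering, coverage overdispersion, methylation
bimodality and beta-binomial noise, but not: CpG-island structure correlated
with promoters (CpG density is homogeneous along the genome), bisulfite
conversion failure, strand asymmetry, SNP contamination, copy-number or
mapping artefacts, or biological replicate variance beyond the beta-binomial
dispersion. Consequently, passing recovery tests validates the pipeline's
arithmetic and bookkeeping under the stated noise model — not the adequacy
of a pure effect-size threshold for noisy real-world designs, where the
simulated null shows substantial false-call rates at shallow coverage.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere internally; BED is converted
  at the I/O boundary. Overlap of inclusive intervals is
  `a.start ≤ b.end and b.start ≤ a.end` (touching at one bp counts).
* The Bismark percentage column is ignored for computation; a discrepancy
  beyond 0.5 versus the counts raises a warning and the counts win.
  Outputs write floats to 4 decimals, and re-writing a read-back table is
  byte-identical.
* Histogram bins are left-closed right-open over [−100, 100] with the final
  bin closed; a Δ of exactly −5 falls in [−5, 0).
* Zero pooled coverage is an error rather than a NaN — it cannot occur
  after the scoreability filter, so reaching it indicates a pipeline misuse.
* Chromosome order is lexicographic throughout ("chr10" < "chr2"); it is a
  presentation choice and affects no statistic.
* Empty intersection of samples aborts with a chromosome-naming hint;
  empty annotation yields all-intergenic labels with no distances.

## Problem sizes

Default verification runs use the 2 × 10 Mb / ~50k CpG genome (seconds per
simulation); oracle-equivalence checks use 500–1,000 randomized small
instances against brute-force or graph-component references. These sizes
give stable statistics (e.g. recovery metrics over 200 planted regions)
while keeping the full suite fast enough to run habitually.

## Known limitations

* The conservation statistic reports both orientations and a bp Jaccard but
  implements only overlap-based matching; reciprocal-overlap thresholds are
  available, breakpoint-aware matching is not.
* GTF parsing is deliberately minimal (transcript/exon rows,
  `transcript_id`/`gene_id` attributes); full GTF/GFF3 semantics are out of
  scope.
* The annotator assigns one label per region; regions straddling, say, a
  promoter and an exon report only the higher-priority context.
* No strand-resolved (CpG-dyad) analysis: input rows are taken as loci
  exactly as given.
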