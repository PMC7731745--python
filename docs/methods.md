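# Methods

## Study design the package models

Two precursor cell populations (adipogenic and myogenic) are sampled from
the skeletal muscle of the same animals (default three), giving a paired
two-group design with six libraries. Methylation is assayed by reduced
representation: MspI digestion (C^CGG), selection of 225–290 bp fragments,
bisulfite conversion, and per-CpG counting. Only CpGs inside the kept
fragments are observable — RRBS coverage is fragment-driven and therefore
concentrated in CpG-dense territory. Expression enters as a replicate table
for the same two groups.

## The differential test

Counts are strand-collapsed to CpG dyads, filtered to autosomal sites with
depth strictly greater than 10 in every sample, and pooled into fixed-width
windows (default 100 bp, non-overlapping, ≥ 3 covered CpGs). The tested
statistic per window and sample is the pooled coverage ratio
Σmeth/Σtotal. The paired t-test runs on per-animal differences with
df = n_animals − 1; BH adjustment is applied once, genome-wide, over all
tested windows. A window is a DMR when |Δ| ≥ `delta_min` (0.03, read as
3 absolute percentage points) and q < `q_max` (0.05).

Two deliberate conventions:

- **Zero-variance differences.** With n = 3 pairs and integer counts, ties
  happen. If every per-animal difference is identical and nonzero, p := 0
  (the t limit as the variance estimate → 0); if identically zero, p := 1.
  Ties are detected exactly on the difference vector, not via `sd == 0`,
  because floating-point cancellation never yields an sd of exactly zero.
- **Alternative count mode.** `test_windows(..., mode="normalized_counts")`
  tests methylated counts divided by median-of-ratios size factors
  (computed on per-site totals) instead of levels. It exists because the
  normalization step is part of the published workflow; the level mode is
  the default since an absolute percentage difference is only well defined
  on methylation levels, and the coverage-ratio level is normalization-free.

Statistical machinery is delegated where a standard tool exists: the t and
Mann–Whitney tests and the hypergeometric tail come from scipy, BH from
statsmodels, hierarchical clustering (Euclidean, average linkage) from
scipy.cluster; tests cross-check BH, digestion, CGI search and closest-gene
linkage against independent brute-force oracles.

## CpG islands and the feature model

Islands are regions > 200 bp with GC ≥ 0.5 and obs/exp CpG ≥ 0.6
(obs/exp = N_CpG·L/(N_C·N_G); N bases are excluded from all counts).
Detection flags every 200-bp window (1-bp step) passing GC and obs/exp,
merges overlapping flagged windows, and — when a merged region does not
itself pass — trims it to its longest (leftmost on ties) passing
sub-interval. On sequences up to 2 kb this matches an exhaustive
maximal-subinterval search, which the tests run verbatim. Shores are the
2-kb island flanks, clipped to chromosome bounds, island overlap removed,
overlapping shores merged.

DMRs are assigned a single category by midpoint with precedence
promoter (P1: TSS..−200, P2: −200..−1500, P3: −1500..−2000, strand-aware) >
5′UTR > 3′UTR > first exon > other exon > first intron > other intron >
distal intergenic. Midpoint assignment guarantees the category counts
partition the DMR set, so feature percentages sum to 100. Genes are
collapsed to their longest transcript; "first" exon/intron is in
transcription order. Closest-gene linkage measures the bp gap to the gene
span (0 when overlapping), breaking ties by midpoint-to-TSS distance, then
lexicographic gene id; linking never crosses chromosomes.

## Expression integration

When replicates are supplied, fold change is the ratio of group means and
the FDR comes from a two-sided Welch t-test on log2 values plus BH — a
minimal, transparent substitute for an upstream RNA-seq pipeline the
package does not re-implement. DEGs use strict thresholds FC > 2 or
FC < 0.5 with FDR < 0.05. Co-different genes are DEG ∩ DMR-linked genes; a
gene linked to DMRs of both directions takes the direction of its
largest-|Δ| DMR for its quadrant, while the DMR-level tally keeps every
link. The per-category fold-change comparison between hyper- and
hypo-linked genes uses a two-sided Mann–Whitney test (exact for small
arms), chosen for robustness to fold-change skew; arms with fewer than 3
genes are flagged not testable. Over-representation analysis is the
one-sided hypergeometric upper tail against user-supplied GMT sets, BH
across sets, with the universe defaulting to all detected genes.

## The synthetic-data generator

The generator emulates the study conditions: 3 animals × 2 groups, mean
per-CpG depth 50 (gamma-Poisson overdispersed, Var = μ(1 + 0.15 μ);
dispersion 0 degenerates to Poisson), bisulfite conversion 0.995 with
failures appearing as methylated reads at rate
m + (1 − m)(1 − conversion), a hypermethylated baseline of 0.75 that dips
to 0.15 at TSSs (linear ramp within ±500 bp) and inside CGIs, a per-animal
N(0, 0.05) logit-scale effect shared by both cell types of the same animal
(what makes the design paired), and planted DMR windows of ±0.40.

Layout choices the source study does not determine, fixed here once:

- **Genome scale**: 3 chromosomes × 700 kb — large enough that a default
  run tests > 2000 windows, small enough that a full simulate-and-call
  cycle takes well under a second.
- **MspI geometry**: cut sites are laid down on a randomized grid whose
  spacing puts ~45 % of background fragments inside the 225–290 bp
  selection band, mimicking the fragment-size enrichment an RRBS protocol
  is built around; islands carry internal sites at 225–290 bp spacing and
  are therefore densely covered, as in real RRBS.
- **Background sequence**: i.i.d. at GC 0.42 with CpG dinucleotides thinned
  to 0.45 of random expectation (genome-wide obs/exp ≈ 0.45, CpG-depleted
  like a vertebrate genome).
- **Planted CGIs**: 60 islands of 800–1600 bp built from shuffled 25-bp
  blocks with fixed composition (GC 0.56, two CpGs per block, obs/exp ≈ 1),
  flanked by 250-bp CpG-free AT-rich buffers so the island boundary is
  crisp; each island is re-verified against the three criteria before the
  genome is emitted. The buffers bound the detector's window-resolution
  overshoot, giving planted-vs-detected interval Jaccard ≈ 0.93.
- **Planted DMRs**: 250 windows (~10 % of tested windows), placed on
  100-bp tiles holding ≥ 8 observable CpGs, centred at 0.5 ∓ Δ/2 so both
  group levels stay inside (0, 1). Placement density and the CpG floor are
  the conditions under which a 2-df paired test can work at depth 50: a
  ±0.40 shift in a window pooling ≥ 400 reads yields a noncentrality far
  above the BH threshold, and a planted fraction near 10 % keeps the
  step-up threshold generous. Whole-window planting makes sensitivity and
  FDR well defined against the tested units.
- **Non-CpG controls**: 2000 cytosine sites with true methylation 0 are
  emitted per study (pooled depth ≈ 6 × 10⁵), because a conversion ratio
  is reported in such studies without an estimator being stated; here it is
  unmethylated/total at non-CpG sites, per sample and pooled.
- **Expression**: 120 genes, log2 abundance U(3, 10), replicate noise
  N(0, 0.25) on the log2 scale, 30 planted DEGs at |log2FC| = 2 with
  balanced signs.
- **Seeding**: one top-level seed; every stage draws from its own
  deterministically derived substream, so regenerating any stage alone is
  byte-identical to regenerating it inside the full run.

What the generator does **not** emulate: read-level error and mapping bias,
fragment-end CpG repair artefacts, non-binomial cell-population
heterogeneity, correlated methylation between neighbouring windows, CNVs,
and any genuine biology linking methylation direction to expression
direction (planted DMRs and DEGs are independent, so co-different counts in
simulation reflect chance overlap). Passing tests therefore demonstrate the
*inferential machinery* — calibration under the null, recovery of planted
effects, correctness of the annotation geometry — not that real RRBS data
meet the model's assumptions.

## Numerical and degenerate-input conventions

Levels at zero total are missing (NaN), and windows with a missing pair
member are excluded with a log line. Size factors require at least one
site with positive totals in every sample. BH validates p ∈ [0, 1].
Empty inputs produce empty, well-formed outputs (empty BED, empty FASTA,
zero-count feature table). GTF is read 1-based inclusive and converted to
the internal 0-based half-open convention; BED is native half-open. The
depth filter's "> 10" is strict. DMR BED scores are −log10 q clipped to
[0, 1000].

## Problem sizes used by the test suite and acceptance script

Null calibration runs one default-size study (~2100 tested windows) plus 20
null seeds; DMR recovery averages 20 seeds (~43 000 windows in total); DEG
recovery 20 seeds × 120 genes; CGI recovery 10 single-chromosome genomes of
200 kb; oracle sweeps use 1000 random p-vectors, 200 digestion strings and
200 closest-gene queries. The full suite runs in well under a minute.

## Known limitations

- With n = 3 pairs the t-test has 2 degrees of freedom; detection of
  effects much smaller than ±0.40, or in windows pooling < ~400 reads, is
  intrinsically poor, and the package makes no attempt to hide that.
- No merging of adjacent significant windows by default (an optional
  same-direction merge is provided); reported DMR counts are window counts.
- The expression module's Welch-on-log2 test is a stand-in for a dedicated
  count-based RNA-seq model and should not be used for real low-count data.
- CGI detection resolution is bounded by the 200-bp window: boundaries can
  overshoot into flanking sequence by up to ~1 window width when flanks are
  not strongly AT-biased.
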