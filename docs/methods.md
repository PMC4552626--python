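# Methods

## Design

The package implements the promoter-centric RRBS differential-methylation
workflow used for paired (twin) case–control designs, as a library
(`src/twinmeth/`) driven by narrative analysis scripts (`analysis/`). Every
computational step lives in the library so the tests and the acceptance
script exercise exactly the code the drivers run.

## Methylation calling

A cytosine report row carries strand-aware methylated/unmethylated read
counts at a 1-based position. Calling retains CpG-context rows with coverage
≥ `min_coverage` (default 20 reads) and computes
percent = 100·m/(m+u). Two deliberate conventions:

* **Base quality is out of band.** Counts are assumed produced under a
  Phred ≥ 20 filter by the upstream extractor; the reader records this
  assumption instead of re-implementing base-level logic.
* **Duplicates are errors.** Two rows for one (chrom, pos, strand) indicate
  a malformed file and raise, rather than being silently summed.

Destranding (merging the − strand record at p with the + record at p−1,
reporting the dyad at the + position) is available but **off by default**:
per-strand accounting matches the common extractor default, and the choice
is exposed because published pipelines differ. Internally coordinates are
0-based half-open; file I/O preserves the 1-based report convention and BED
stays 0-based, so off-by-one ambiguity is confined to the parsers.

The bisulfite conversion rate is estimated from non-CpG cytosines (presumed
unmethylated): 100·Σu/Σ(m+u) over CHG/CHH rows, unfiltered by coverage.
Technical-replicate concordance is the Pearson correlation of percent values
over shared sites (≥ 3 shared sites, non-constant vectors required).

## Region scoring

A region's level is the count-pooled density — methylated C reads over total
C reads across its passing CpGs — **not** the unweighted mean of per-CpG
percents; the two agree only under equal coverage, and the pooled form is
what a 2×2 count test uses. A region needs ≥ 3 CpGs each at ≥ 20×; below
that it is reported missing, never zero, and missing regions are skipped
(not imputed) in downstream tests.

Annotation: promoters are (−2000, +1000) around the TSS, mirrored for −
strand genes (TSS = txEnd); promoters identical in coordinates (divergent
gene pairs) are deduplicated, with gene symbols joined by ';' and re-expanded
for reporting. CpG shores are the 2-kb island flanks minus any island
overlap; iLADs are the per-chromosome complement of LADs; introns default to
gene span minus exons.

## DMR testing

Replicate counts are summed within each group ("pooled testing"), then each
shared promoter is tested with a two-sided Fisher exact test on
[[m_case, u_case], [m_ctrl, u_ctrl]]. The two-sided p sums hypergeometric
probabilities of all tables with the observed margins whose probability is
≤ the observed table's, with 1e-7 relative slack for floating ties — stated
explicitly because two-sided Fisher conventions differ between packages. A
zero margin admits only one table and returns p = 1. The implementation uses
log-gamma arithmetic; tests verify it against an exact integer-rational
enumeration for every table with row margins ≤ 30 and against
`scipy.stats.fisher_exact` on random tables.

Multiple testing uses a sliding-linear-model (SLIM) q-value: the empirical
CDF of the p-values is evaluated on the λ grid {0.01, 0.05, …, 0.95}; on
windows of 6 grid points with λ ≥ 0.4 (where true signal is rare under the
two-group mixture model) straight lines are fitted to the CDF, and π₀ is the
median window slope clipped to [0, 1]. Then qᵢ = π₀·p₍ᵢ₎·n/rank, monotonized
from the largest p down; with fewer than 20 p-values π₀ is fixed at 1
(estimating a mixture from a handful of p-values is noise). Plain
Benjamini–Hochberg is available as `q_method="bh"` and serves as the
cross-check: on uniform nulls π₀ ≈ 1 and SLIM reduces to BH.

A promoter is a DMR when q ≤ 0.001 and |Δ| ≥ 25 percentage points
(Δ = percent_case − percent_control; positive = hypermethylated case).
The joint threshold matters: with thousands of pooled reads the Fisher test
detects sub-point differences, so the effect-size floor is what keeps
biologically trivial (and inter-individual) differences out.

The cascade treats DMR identity as the exact promoter key — all comparisons
are tested on one promoter universe, so overlap-based matching is
unnecessary; a mismatched universe raises. Stage 1 is the focal comparison's
DMR set; stage 2 removes DMRs also called in any control comparison; stage 3
keeps those also called in the unrelated comparison. Stages are nested by
construction and hyper/hypo tallies use the focal comparison's signs.

## Metagene profile

Genes are mapped strand-aware onto: upstream flank TSS−10 kb…TSS+1 kb (44
fixed 250-bp bins), body TSS+1 kb…TTS−1 kb (60 proportionally scaled bins),
downstream flank TTS−1 kb…TTS+10 kb (44 bins), plus one pooled intergenic
remainder row (per-chromosome complement of all gene models). Genes whose
body would be empty (span ≤ 2 kb) are skipped and counted. Bin counts are
pooled across genes per condition; density = 100·m/(m+u) and fold change =
density_case/density_control, flagged missing (no pseudocount by default)
where a denominator is empty or the control density is zero. The bin
counts (44/60/44) are a package choice — fine enough to resolve the TSS
peak, coarse enough to keep hundreds of CpGs per bin in the simulated
cohorts. Mann–Whitney feature comparisons use the exact null distribution
for untied samples up to n = 50 per group and the tie-corrected normal
approximation otherwise; the per-CpG difference histograms are computed in
both orientations, with the reversed orientation binned right-closed so the
two histograms are exact mirror images even for edge-valued differences.

## Expression integration

Quantile normalization replaces each column's order statistics by the
across-column rank means, ties receiving the mean of their rank range (hence
idempotent, and exact identity for already identically-distributed columns).
Log2 fold changes use replicate means; zero means are flagged missing rather
than infinite, with an optional pseudocount. Methylation–expression coupling
is the Pearson correlation over complete gene pairs. Enrichment is the
upper-tail hypergeometric test of a query list against GMT gene sets
intersected with a universe that defaults to genes with a scored promoter —
a stated choice, since published analyses rarely say which universe they
used and FDR values are database-version dependent.

The packaged fixture of the published methylation/expression table keeps the
printed values verbatim, including one promoter whose methylation difference
is printed differently in two tables (55.30 vs 60.58); no reconciliation is
attempted. Recomputing the fibroblast-column Pearson correlation from the
printed values yields +0.106, not the printed −0.86 — one gene pairs a large
positive methylation delta with a positive expression fold change and
dominates the small n = 7 sample — while the iPSC columns reproduce their
printed −0.56 exactly. The package reports the recomputed values.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
sequencing chemistry (no reads, no fragment-size model):

* **Layout.** Evenly spaced 20-kb genes with alternating strands; 3-kb
  promoters each containing a 1-kb CpG island at the TSS; 15–25 (default)
  clustered CpGs per promoter plus ~1 background CpG/kb, mirroring RRBS
  enrichment for CpG-dense regions; LADs as alternating 100-kb blocks;
  ~0.5 non-CpG cytosines/kb with true methylation 0.2% to exercise
  conversion-rate estimation.
* **Counts.** Coverage is negative binomial (mean 30, dispersion 0.1;
  variance = μ + 0.1μ²) because RRBS coverage is overdispersed; dispersion 0
  degrades to Poisson. Methylation is beta-binomial: a latent proportion per
  CpG from a class beta prior — promoters/islands Beta(1.5, 13.5) (mean
  0.10), background Beta(8, 2) (mean 0.80), reproducing the bimodality of
  real methylomes — then binomial counts per sample.
* **Effects.** The case twin's promoter-class CpGs get the global shift plus
  any planted DMR delta, applied on the percent scale and clamped to
  [0.01, 0.99] before sampling. Promoters carrying a planted *negative*
  delta draw a mirrored baseline (p → 1−p): hypomethylation is only
  realizable from a methylated baseline, exactly as in real promoters.
* **Individuals and replicates.** A twin pair shares one latent methylome;
  unrelated individuals draw independent ones (which produces realistic
  inter-individual promoter differences of a few points — the reason the
  cascade's unrelated comparison needs the effect-size floor). Technical
  replicates re-measure the same individual with independent count draws
  plus per-CpG Gaussian jitter, sd 10 points: with the bimodal latent
  variance this lands replicate correlations near 0.90, the regime reported
  for real RRBS technical replicates. Because the jitter is mean-zero and
  shared-latent, it cancels in pooled densities and group means.
* **Streams.** Every sample has its own RNG stream spawned from the master
  seed, so adding samples or comparisons never perturbs earlier ones, and a
  fixed seed reproduces byte-identical outputs.
* **Expression.** Per-gene true log2FC = −coupling·Δ + N(0, σ) (default
  slope 0.05/point, σ = 0.3 — promoter hypermethylation represses), around
  which 4 control and 3 case replicates scatter log-normally.

What the generator does **not** emulate: mapping artifacts, M-bias,
fragment-end effects, copy-number-driven coverage differences, and spatial
correlation of methylation along a region beyond the shared promoter delta.
Passing tests therefore demonstrate the pipeline's statistical behaviour
under its own model assumptions, not performance on real libraries.

## Problem sizes

The recovery analyses use 2000 promoters of 20 CpGs at 30× with two
replicates per group and 100 planted DMRs at |Δ| = 40 (85 hyper / 15 hypo);
the global-shift analyses use 2000 CpG-dense promoters (60–80 CpGs) at 60×
on two 52-Mb chromosomes so that every metagene bin pools enough reads for a
±3% fold-change resolution; the narrative cohort in `analysis/` uses 400
promoters for fast iteration. These sizes were chosen once as a power
calculation under the generator's noise model.

## Known limitations

* SLIM's π₀ estimator assumes a p-value CDF that is linear in the upper tail;
  heavily discrete Fisher p-values (tiny counts) make it conservative-biased
  downward, which is why BH is the designated cross-check and the null
  calibration is asserted on uniform p-values.
* The replicate-jitter clamp at [0.01, 0.99] adds a small upward bias to
  very low methylation levels; it is shared between groups with a common
  latent methylome and cancels in differences, but single-sample absolute
  levels near 0% are biased by up to ~2 points.
* Cascade identity is exact-key only; comparing DMR sets called on different
  promoter universes (e.g. different annotation releases) is unsupported by
  design.
* Real-data scale quantities (genome-wide DMR counts, multi-million-CpG
  coverage tallies) require the original sequencing data and are outside
  what the synthetic cohort can or should reproduce.
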