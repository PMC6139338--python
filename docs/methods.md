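# Methods

## The metagene model

Every gene is reduced to a single span from translational start to stop
codon (no exon structure) plus a 3 kb upstream flank. The flank is divided
into 20 bins of 150 bp (F1 most distal from the start codon) and the gene
body into 10 equal segments (B1..B10, 5′→3′), so genes of different
lengths share a 30-bin coordinate system. Coordinates are 0-based
half-open internally; GFF3 (1-based inclusive) and WIG (1-based starts)
are converted at the I/O boundary, and GFF3 features sharing an ID are
collapsed to their min-start/max-end span.

Bin arithmetic runs in a strand-oriented coordinate `d` — base pairs from
the translational start, negative upstream — with real-valued bin edges.
Each probe contributes its value to the bin containing its midpoint
`(start + end)/2`; a midpoint exactly on an internal edge goes to the 5′
(lower-index) bin. The 5′ tie rule, rather than "lower genomic
coordinate", is what makes per-gene profiles exactly invariant under
mirroring the genome (reverse coordinates, flip strands, reverse the
track); for plus-strand genes the two rules coincide. Midpoint assignment
(rather than overlap-weighting) is the simplest deterministic rule and is
adequate when probes are short relative to bins, as tiling probes are.
Flank bins falling outside the chromosome are clipped or dropped; a gene
on a chromosome absent from a track yields an all-missing profile with a
warning, and genes with fewer than `min_probes` (default 5) probes overall
are excluded from cohort profiling with a log entry.

## Aggregation and error bars

Aggregation is per-gene-first: probes → per-gene bin means → cross-gene
mean, sample SD (n−1) and SE = SD/√n-genes per bin, where n counts genes
with a non-missing value in that bin (bins with fewer than two
contributors get missing SD/SE). The alternative — pooling all probes per
bin across genes — was rejected because the SE definition used throughout
(cross-gene SD over √n-genes) only makes sense with per-gene values; both
readings were considered and the per-gene one is asserted by the tests.

Smoothing is a centered 5-bin moving average, truncated at the vector
edges, skipping missing values within each window. Centering and
truncation were open choices; centered truncation is symmetric and loses
no bins. Smoothing is applied to the aggregate mean and SE vectors (the
curves one plots, and the default ratio input); a raw-curve option is
kept.

## The promoter-bias ratio

`peak_nadir_ratio` takes the maximum of the (smoothed by default)
aggregate curve over the promoter window and the minimum over the
gene-body window, with ties broken toward the lower bin index. The default
promoter window is F1..F20 plus B1 — the peak sits at the start-codon
boundary, which the discrete binning can place on either side of the
F20/B1 edge — and the default nadir window is B2..B10, excluding B1 so the
promoter peak cannot bleed into the nadir search. Both windows are
configurable. The nadir must be positive (the data are fold enrichments).

The ratio's standard error is first-order delta-method propagation
assuming independence of peak and nadir: they come from distinct bins and
gene weightings, and no covariance estimate is defined for the aggregate
curve. Two comparison methods are provided and reported side by side,
because a printed "ratio ± SE with a t-test" presentation does not pin
down the test: `z_propagated` (normal z on the propagated SEs, matching
the ± SE presentation) and `welch_per_gene` (Welch unequal-variance t on
per-gene smoothed ratios, with genes lacking a raw peak or nadir window or
a positive nadir excluded and counted). Neither is claimed to reproduce
any particular published p-value exactly.

## Responsiveness

Delta signal is the per-gene difference of unsmoothed promoter-window
means, fed − starved; no smoothing statement exists for this quantity, so
the raw means are used. Records are ranked descending (rank 1 = largest
delta) with ties broken by gene id for determinism. Rank bins of 100 genes
are drawn from the top, the bottom, and a middle bin centered on the
median rank (ranks ⌊(n−k)/2⌋+1 … +k); the centered placement of "middle"
is a documented choice, since only "top, middle, bottom" is specified. For
827 ranked genes with k = 100 the middle bin is ranks 364–463.

Expression responsiveness floors linear levels at 1.0 (to keep fold
changes finite on near-zero values; low-value handling is otherwise
unspecified) and calls a gene responsive when |log2(b/a)| ≥ 1.5, an
inclusive threshold — log2 FC exactly 1.5 (2.83-fold) is a call.

## Overlap testing

Venn-region counts are exact set algebra over two or three sets sharing
one universe. Enrichment of a pairwise overlap k is the one-sided Fisher
exact test on [[k, |A|−k], [|B|−k, N−|A|−|B|+k]], i.e. the hypergeometric
upper tail P(X ≥ k); a two-sided variant is available by flag. The
universe N is a required, logged parameter with no silent default —
overlap p-values are meaningless without an explicit universe, and the
natural choice (the annotation's gene count) must be supplied at load.

## Motif enrichment

8-mers are counted in overlapping windows; windows containing N are
skipped and excluded from the window total. With reverse-complement
collapsing, a k-mer and its reverse complement share the lexicographically
smaller key, so GAGAGAGA/TCTCTCTC and ACACACAC/GTGTGTGT are single
motifs. Enrichment of promoter (foreground) counts over background is an
upper-tail binomial test at the background per-window rate, floored at
0.5/bg-windows for motifs unseen in the background, with
Benjamini–Hochberg correction across all observed motifs. The binomial
ignores the overlap dependence of repeat runs; that dependence makes
planted repeats look *more* significant than an overlap-aware null would,
which is acceptable here because the claim being supported is qualitative
(the repeats surface at the top of the ranking), and any calibrated use
should treat the q-values as approximate.

## The synthetic-data generator

`metachip.simulate` emulates a whole-genome tiling-array ChIP experiment:
non-overlapping genes on alternating strands with ≥ 3 kb upstream
clearance (gaps are widened as needed; a configurable edge fraction may
sit near the chromosome start), probes tiling every 50 bp, and expected
probe values

    b + A(genotype, condition) · m_gene · exp(−(d − μ)² / (2σ²)) + slope·d/1000

for marked genes (baseline b = 1 elsewhere), with additive Gaussian noise
(SD τ, default 0.2) floored at 0.01. Additive noise keeps the bin-mean
oracle exact in expectation, which multiplicative noise would not. The
bump center μ = −150 bp places the peak just upstream of the start codon,
and σ = 400 bp gives the flank-heavy shape with some bleed into the first
body decile, as promoter marks show. `m_gene` is an optional per-gene
lognormal enrichment propensity (unit mean, dispersion `amplitude_cv`,
default 0) shared across all tracks of one genome, so the same genes run
hot in every condition.

Defaults (827 genes of 1–3 kb, 50 bp probes, b = 1, A = 1.3, τ = 0.2,
marked fraction 1.0) are the cohort conditions the test suite and the
recovery properties use. Gene lengths of 1–3 kb and intergenic gaps of
3–5 kb are typical of a compact metazoan genome. Promoter FASTA (500 bp,
strand-oriented) optionally carries (GA)₁₅/(AC)₁₅ runs in a configurable
fraction of marked promoters. Expression matrices plant per-class log2
effects (±2.0 by default) on a lognormal base level with 0.2 log2 noise
per sample.

Because binning, averaging and smoothing are all linear in probe values,
the expected aggregate profile at amplitude A is an affine combination of
the A = 0 and A = 1 noise-free profiles; `calibrate_amplitude` exploits
this to solve, by root finding, for the amplitude whose noise-free
aggregate ratio equals a requested value. The emulated study in
`analysis/` and `scripts/acceptance.py` calibrates its six amplitudes this
way against the nominal ratios 2.30/2.20 (wild type), 2.11/2.62
(*O*-GlcNAcase mutant) and 1.81/1.57 (transferase mutant, Pol II), and
uses `amplitude_cv = 2.5`, chosen so the propagated SEs of an 827-gene
cohort land near ±0.08–0.09 — the scale real tiling-array cohorts show —
rather than the implausibly tight ±0.01 of a homogeneous cohort. A
long-tailed enrichment distribution is also what a thresholded "marked"
gene list implies.

What the generator does **not** emulate: probe-level hybridization physics
and dye bias, replicate array structure, correlated noise along the
chromosome, overlapping or nested genes, exon structure, and any coupling
between promoter signal and expression level. Passing tests therefore
demonstrate correctness of the statistical machinery under a known model,
not robustness to array artifacts.

## Numerical choices and degenerate inputs

Ratio windows must be non-empty, disjoint and (for the aggregate ratio)
fully non-missing; a non-positive nadir is an error. Comparing two ratios
that both have zero SE returns p = 1 when equal and p = 0 with a warning
when not. Mean computation accumulates probe values in coordinate order,
so mirrored genomes agree to float accumulation error (~1e-15 relative),
not bit-exactly. Profile tables serialize at 9 significant digits with
`NA` for missing values and round-trip losslessly at that precision. Track
seeds derive from the top-level seed plus CRC32 of the condition and
genotype labels, so every track is reproducible in isolation and distinct
labels get independent noise streams.

## Problem sizes

The test suite and the acceptance script run cohorts of 827 genes (10
seeds for recovery properties), 400-replicate null calibrations on a
120-gene toy genome, exhaustive hypergeometric checks for all universes
N ≤ 60, 2000-gene expression cohorts, and 500×500 bp motif sets — sizes
chosen so known-truth recovery is sharp while the whole suite stays fast
on one CPU.

## Known limitations

The per-gene Welch comparison treats per-gene ratios as exchangeable
across genes; gene-length-driven differences in probe counts make the
per-gene ratio variance mildly heterogeneous, which Welch absorbs but a
paired design would exploit better. The aggregate z test inherits the
independence assumption of the delta method. The binomial motif test is
anti-conservative for tandem repeats in the foreground (see above). The
delta ranking uses promoter means, not peaks; with very sparse probes the
mean is the more stable choice but the two can disagree on individual
genes.
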