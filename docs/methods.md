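# Methods

## Scope and model of the data

The package implements the downstream arm of a differential-epigenome
analysis: given summit-annotated peak sets, binned coverage (enrichment)
tracks for two conditions, an enhancer atlas, gene annotation, region
sequences and a gene-expression table, it scores summit-centered
differential acetylation, calls super-enhancers, quantifies atlas overlap
and genomic-element enrichment, tests known-motif enrichment, and extracts a
cross-clone differential-expression consensus. Read alignment, peak calling
and de novo motif discovery are deliberately upstream of this package;
whatever "enrichment" the supplied tracks encode (raw pileup or
input-normalised fold enrichment) is what the statistic is computed on.

Coordinates are 0-based half-open throughout (BED convention); strand is
carried but ignored by overlap arithmetic, since ChIP enrichment is
unstranded. All overlap criteria are "at least one nucleotide" unless a
`min_bp` argument says otherwise.

## Differential score

For a peak with summit s, the score aggregates the per-bin ratio
f(k) = (KO_k + ε)/(WT_k + ε) over the bins covering the closed window
[s − w, s + w], w = 15 000 bp by default, ε = 1.0 per bin:

* `mean_of_ratios` (default): Fc = (1/N) Σ f(k). This is the per-position
  ratio sum normalised by the number of bins summed, which makes the
  aggregate scale-free and directly comparable to a fold-change cutoff
  (|log2 Fc| ≥ 1 by default) regardless of window size or track resolution.
* `ratio_of_sums`: Fc = (Σ KO_k + ε)/(Σ WT_k + ε), exposed because the two
  readings of a per-position ratio sum are both defensible; it is exactly
  antisymmetric under swapping the tracks.

Windows are clipped at chromosome ends and `n_bins` records the bins
actually used, so short chromosomes carry no edge bias. Bin width defaults
to 50 bp — typical coverage-track resolution; the symmetric pseudocount
keeps empty-vs-empty bins at ratio 1 and bounds the score for empty windows.
Output is sorted by |log2 Fc| descending with genomic order as the
tie-break, for determinism. For H3K27ac the up set is the hyper-acetylated
one; for H3K27me3 the down set is the de-methylated one.

## Normalization check

Peak signals common to two samples are placed on the MA plane after a
pseudocount (M = log2(a/b), A = ½·log2(a·b)) and a robust Theil–Sen line is
fitted. Two deliberate choices:

* **Anchor at the median A.** The reported line is
  M = intercept + slope·(A − median(A)). The classic A = 0 intercept sits
  several log2 units below the data, so slope noise alone (≈0.013 at
  n = 500) corrupts it by ~0.1; at the anchor the intercept is the log2
  offset at a typical intensity and coincides with the classic intercept for
  a pure global scaling (slope 0), which is the case the check exists for.
* **Trimming before the fit (pipeline stage).** Peaks with
  |M − median(M)| above the differential cutoff are excluded from the fit.
  Genuinely differential regions are biology, not scaling; when they are
  abundant (25% of peaks under the default study conditions, all near
  M = +2 with elevated A) they exceed the effective breakdown of both
  Theil–Sen and repeated-median slopes and would falsely trigger rescaling.
  A true global scaling shifts every M equally and passes the trim intact.

"Very similar regression lines" is made operational as |slope| ≤ 0.1 and
|intercept| ≤ 0.25 (log2); within these tolerances no rescaling is applied —
the branch the pipeline takes under its default conditions. When rescaling
is needed, each bin is multiplied by 2^(intercept + slope·(A(v) − anchor)),
which flattens the refitted line to |intercept| < 0.02 in the pure-scaling
case.

## Super-enhancer calling

Constituents are H3K27ac peaks overlapping an H3K4me1 peak (signals
preserved). Stitching merges constituents whose gap is at most 12 500 bp
(inclusive boundary, fixed for determinism; the published convention for
this distance). Ranked total signals are scaled to the unit square and the
cutoff is the elbow — implemented as the point minimising y − x, with the
"first discrete slope > 1 scanning from the left" rule available as an
option. The two rules coincide on convex curves; the y − x minimiser is the
default because a single anomalous order-statistic gap in the low-signal
bulk can trip the left-to-right scan arbitrarily early. An all-equal signal
curve is the degenerate diagonal: no enhancer exceeds the trend, so there
are zero super-enhancers and the cutoff sits at the maximum. Signal ties
rank in genomic order. Calling is invariant to a global rescaling of all
signals.

## Atlas and enrichment

The senescence SE atlas (SES) is the union of SE interval sets from
independent senescence models, merged (overlapping or book-ended intervals
join). Element classes are made disjoint by clipping each class with all
higher-precedence classes; the default precedence — SES, SESM, TES,
promoter, exon, intron, intergenic — puts the enhancer classes first
because they are the objects of study, and is configurable because any
single-label partition must choose. Intergenic is the genomic complement.
Promoters are TSS ± 2 kb, clipped at chromosome bounds.

Regions are assigned to the unique class containing their *summit* (the
anchor of every windowed analysis here); assignment is therefore a
partition, and Σ fold·expected over classes equals 1 when every region is
assigned. Fold enrichment per class is observed region fraction divided by
the class's share of the genome; for real human data the genome length
constant 3 184 709 445 bp (female haploid) is provided, while synthetic runs
use the generated genome size so simulations stay self-consistent.

Gene–SE association is "closest active": among genes whose expression
passes the activity rule (default: baseline at or above the gene-wise
median; an explicit threshold or a precomputed flag can substitute), the
gene with the smallest TSS distance wins, distance 0 if the TSS lies inside
the SE, ties broken by smaller TSS then lexicographic id. SEs on
chromosomes without an active gene report "unassigned".

## Motif analysis

PWMs are scanned on both strands; a window scores Σ log2(p_base/bg_base)
and hits at ≥ 80% of the PWM's maximum achievable log-odds (a standard
heuristic; no scan threshold is inherited from upstream discovery tools).
`N` bases contribute 0 bits (background). Built-in PWMs encode the AP-1 TRE
consensus TGA(C/G)TCA and the NF-κB consensus GGGRNNYYCC with exact
probability rows; user motifs load from MEME minimal format. Enrichment is
region-level — a region counts once with ≥ 1 hit — which is robust to
region length, and uses a one-sided hypergeometric test with significance
at p < 0.5 × 10⁻⁴. Upstream discovery tools model dinucleotide background
and sequence composition, so their numeric p-values are not comparable;
only the selection threshold carries over.

## Expression consensus

DEG calling is strict on both sides (|fold change| > 2, adjusted p < 0.05,
taken literally), on signed linear fold changes. Adjusted p-values are used
as supplied; when only raw p is present, Benjamini–Hochberg is applied per
comparison (the standard choice where the adjustment procedure is not
dictated by the input). The consensus signature is the intersection across
all comparisons restricted to genes whose direction agrees everywhere
(expression programs shared by independent knockout clones move coherently);
the induced fraction is round-half-up of 100·n_up/n_total, the convention
that maps 142 of 230 to 62%.

## Synthetic epigenome generator

The generator emulates the statistical structure this pipeline assumes, on
a small genome (default 4 chromosomes × 5 Mb, 50 bp bins), with every draw
flowing from one seed, so outputs are byte-reproducible.

* **Layout.** Each chromosome is divided into equal blocks, one
  differential-universe peak per block, placed so that summit ± 15 kb
  scoring windows never overlap each other; one auxiliary slot per block
  hosts enhancer units, lineage (SESM) intervals, extra HDAC4 peaks or
  replicate-unique peaks, assigned by a seeded permutation.
* **Tracks.** A baseline enrichment of 10 with triangular bumps at peaks
  forms the mean profile; WT and KO tracks are that profile times unit-mean
  log-normal noise (CV 0.2 by default). Multiplicative log-normal noise
  keeps tracks positive and makes ratio statistics analytically checkable:
  the geometric mean of per-bin KO/WT ratios in a planted window is exactly
  2^planted_log2fc in expectation. A 25% subset of peaks has KO bins
  multiplied by 2^2.0 across summit ± 15 kb.
* **Enhancers.** 300 stitched units: 285 background units whose totals are
  drawn from a bounded uniform signal band (20–60, split over 1–2
  constituents), and 15 planted super-enhancers — clusters of 3–4
  constituents within ≤ 9 kb whose total is 6 × the background median
  (jittered ±10%). The bounded background is deliberate: with a smooth
  unbounded tail (log-normal or gamma) the ranked-curve elbow provably lands
  *inside* the background tail and labels an O(tail-scale) handful of
  background units super regardless of the planted signal, which would make
  planted-recovery truth ill-defined. The pooled stitched-signal
  distribution is still heavy-tailed — through the planted supers, which is
  the feature the caller exploits.
* **Atlas, HDAC4, sequences.** 60 SES intervals (36 over planted
  differential peaks, 24 over null peaks), 50 TES, 20 SESM; HDAC4 peaks at
  20 of the differential SES, 5 null SES, 15 elsewhere; AP-1 planted in the
  sequences of 12 of the 20 HDAC4-bound differential SES — a three-step
  screening funnel (36 → 20 → 12) with exact truth. Sequences are i.i.d.
  uniform A/C/G/T, uppercase, no N; spontaneous AP-1 consensus occurrences
  are scrubbed by resampling (the two consensus variants are mutual reverse
  complements, so forward scrubbing covers both strands), which makes motif
  truth exact rather than statistical. Motif test sets are 100 target and
  100 background regions with planted rates 0.5 and 0.05.
* **Expression.** 1000 genes, half "active" (baseline log-normal around
  200 vs 20); 40 planted DEGs shared across two simulated knockout-clone
  comparisons (60% induced), 20 clone-specific DEGs each, and null genes
  held strictly inside both cutoffs, so consensus recovery is exact.
* **Replicates.** Two replicate peak sets of 60 share a planted fraction
  0.5 (well above the 0.27 QC floor).

What the generator does *not* emulate: read-level sampling noise,
mappability and GC bias, copy-number structure, diploid genomes, correlated
inter-peak background, or a realistic heavy-tailed typical-enhancer signal
continuum (see above). Passing tests therefore demonstrate the correctness
and determinism of the analysis logic under its stated model — not
robustness to every artifact of real sequencing data.

## Problem sizes and numerical choices

Default synthetic runs use 400 peaks / 100 planted differential windows,
300 stitched units / 15 planted SEs, 1000 genes / 40 planted DEGs, 200
motif regions, and 20 Mb of genome — sizes chosen so a full pipeline run
completes in seconds while every recovery statistic is estimated from ≥ 15
planted instances. The enrichment null calibration uses 10 000 uniform
regions over classes covering 7–25% of a 1 Mb chromosome, so each fold's
binomial standard error is ≤ 0.04 and the [0.8, 1.25] acceptance band is
≥ 5 standard errors wide. Scores match a bin-by-bin oracle to 1e−9;
constant-ratio tracks are exact to 1e−9 with a zero pseudocount. JSON
reports are written with sorted keys and no timestamps, so reruns are
byte-identical.

## Known limitations

* The differential score carries no per-region significance; it is a
  fold-change statistic with a hard cutoff, as defined.
* The MA rescaling uses each bin's own intensity as a proxy for the pair
  mean log-intensity; exact for global scaling, approximate for
  intensity-dependent trends.
* Class resolution depends on the declared precedence; alternative orders
  change promoter/enhancer bookkeeping and are exposed as configuration
  rather than resolved by the package.
* Motif p-values assume exchangeable regions; correlated sequences (e.g.
  repeats) would need a matched background, which the caller supplies.
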