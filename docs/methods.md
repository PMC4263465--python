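# Methods

## Coordinates, grids and missing data

All coordinates are 0-based half-open (BED convention); GFF/GTF input is
converted on read, and wiggle's 1-based positions likewise. Signal lives on a
fixed step grid (default 10 bp) per chromosome; the last step may be partial.
When a bedGraph/wiggle interval set is resampled onto the grid, each step
takes the value of the interval covering the step midpoint — lossless for
step-aligned input, and deliberately not an average, since the consumed
tracks are already stepped. Steps covered by no interval are missing (NaN),
and missingness propagates: a step missing in either coverage track is
missing in the ratio, and a missing step contributes nothing (not a zero) to
a smoothing window.

## Enrichment ratio

The published processing chain this package re-implements cites its ratio
computation to earlier work without reproducing it, so the ratio here is the
minimal standard construction: both coverage tracks are scaled to the mean of
their two genome-wide totals (library-size equalization), an additive
pseudocount (default 0.5) is applied, and the ratio is log2:

    r_i = log2((chip_i * s_c + p) / (input_i * s_i + p))

`equalize_totals=False` gives the pointwise ratio; note that with localized
enrichment the equalization subtracts a small constant from every step (the
enriched mass inflates the ChIP total), which is irrelevant to the
percentile-based region calling downstream.

## Median smoothing

Output step i is the median of the defined raw values in a window of
`window_bp` centred on the step midpoint; a step j belongs to the window of
step i iff its midpoint lies in `[mid_i - W/2, mid_i + W/2)`, which for a
50-step (500 bp) window means offsets −25..+24. Windows holding fewer than
`min_points` defined values are set to missing; the presets pair (500 bp, 25)
and (2000 bp, 100). Deterministic tie rule: with an even count of defined
values the lower of the two central order statistics is taken. Windows are
truncated at chromosome ends and the minimum still applies, so edge steps are
often discarded. The implementation is checked value-for-value against a
scalar brute-force reference in the test suite.

## Region calling

The cutoff is the nearest-rank top-percentile value: with n defined values
and top fraction q, the k-th largest value where `k = ceil(n·q)`; every value
≥ the cutoff crosses, so ties all count (a constant track crosses
everywhere). The cutoff is genome-wide over all analysed chromosomes by
default; per-chromosome scope is available. Crossing steps ("data units") are
chained when the genomic gap between their step intervals is ≤ `max_gap_bp`
(200 bp); a candidate region spans first-unit start to last-unit end and is
dropped if shorter than 200 bp or containing fewer than 5 units.

Scoring: the mean over the best run of five *consecutive* steps anywhere
inside the region, using smoothed values whether or not each step crosses the
cutoff; ties go to the leftmost run, and the peak centre is that run's
genomic centre. Runs containing missing steps are skipped; in the degenerate
case where every 5-step run has a gap, run means fall back to the defined
values only. Because sub-cutoff steps may enter the best run, a region score
can in principle fall below the cutoff on pathological tracks; on smoothed
tracks it does not.

## HAS distance profile

Distance is the interval-to-interval gap: zero when a region overlaps *or
abuts* a HAS, so "overlap" is exactly the first bin. Distances are binned
into 8 contiguous bins with an open-ended last bin; the default 5 kb width
makes the last bin ">35 kb", matched to a ~22 Mb X chromosome carrying 263
HAS (mean spacing ~84 kb, i.e. bin width ≈ spacing/17). On the synthetic
1 Mb / 50-HAS chromosome the mean spacing is 20 kb and ±5 kb windows around
the sites would cover about half the chromosome, saturating the control's
first bin; distance profiles on that toy genome therefore use 1 kb bins, the
same spacing-proportional choice. The random control draws positions
uniformly on the chromosome (default 10^4 points, seeded) and treats each as
a zero-length site; the published analysis states no control size, so the
default is chosen to make the control's binomial error negligible relative
to the observed fractions.

Open choices resolved here: distances are measured from region edges (not
peak centres), because overlap defines the first bin; and the control size
is a parameter, not data-derived.

## TSS repeat landscape

The repeat-fraction track holds, per 10 bp step, the fraction of
repeat-masked bp in a 200 bp window centred on the step midpoint (merged
repeat intervals; windows truncated at chromosome ends use the truncated
denominator, keeping values in [0, 1]). The TSS profile pools upstream and
downstream by absolute distance — 20 bins of 1 kb — because the analysis it
mirrors reports unsigned "distance from the TSS"; a strand-oriented signed
mode is available behind a flag. Averaging is gene-first: each gene
contributes one mean per bin, the group statistic is the mean over genes, and
the 95% CI is the normal approximation mean ± 1.96·SE over genes — genes, not
steps, are the independent units. Genes close to a chromosome edge keep their
truncated bins. Wild-type style grouping labels an expressed gene bound iff
any step in its span reaches the top-5% cutoff of the ratio track (ties
cross, so a constant track degenerately labels everything bound — documented
behaviour). Expression flags come from input annotation, never from the
signal.

## Repeat-class enrichment

RPKM uses the library's *genome-mapped* read total as denominator — not the
repeat-mapped total — matching the convention of the analysis being
re-implemented. Multi-mapping reads are counted once per class they hit
(map-all alignment), which over-counts k-mers shared between classes; the
SAM-to-counts helper therefore counts secondary alignments too. The
ChIP/input ratio is the RPKM ratio; classes with zero input RPKM are reported
with an undefined ratio rather than dropped. The 95% CI is a seeded
multinomial bootstrap over reads (B = 1000 by default): reads are resampled
over classes with the observed proportions independently for ChIP and input
and the ratio recomputed; no CI method is stated in the source analysis, so
this is the package's choice. Ranking compares condition pairs by
mutant-ratio over wild-type-ratio with a 2-fold report threshold.

## Synthetic data: what it emulates, and what it does not

The generator plants, under one seeded RNG (fixed seed ⇒ byte-identical
files):

* **HAS analogs** — boxcar fold enrichments (default 50 sites of 500 bp at
  linear fold 4 on a 1 Mb X analog), one site per equal chromosome segment
  with jittered position, hence never overlapping.
* **Pericentromeric gradient** — the ChIP fold rises toward the
  centromere-proximal (right) end as
  `fold(d) = 1 + (max_fold − 1)·exp(−d/decay)` with defaults max_fold 2 and
  decay 100 kb, emulating a gradual increase of enrichment toward the
  centromere.
* **Noise** — per-step Gaussian log2 noise, split evenly in variance between
  the ChIP and input tracks so the log2-*ratio* noise sd equals the
  configured value (default 0.3). Baseline coverage is 100 per step, making
  the 0.5 pseudocount negligible.
* **Genes and repeats** — 400 expressed genes on a 20 Mb autosome analog at
  50 kb spacing, labelled half bound / half unbound; repeat intervals of
  200 bp laid slot-wise within ±20 kb of each TSS at masked-fraction 0.30
  (bound) vs 0.10 (unbound, ratio 3), plus a 2% background elsewhere.
* **Repeat-class counts** — Poisson counts with expectations proportional to
  consensus length, summing to 10^5 repeat-mapped reads per library, with
  planted ChIP folds 5, 3 and 2 for three classes (Hoppel-derived
  PROTOP_B/PROTOP_A and the rDNA non-transcribed spacer analogs) and 12 null
  classes; both libraries report 10^7 genome-mapped reads.

Not emulated: read-level artefacts (fragment-length smearing, mappability,
GC bias — sites are clean boxcars and noise is iid per step), copy-number
structure of polytene tissue, biological correlation between repeat density
and binding (the generator *asserts* the association the analysis is meant to
detect), and expression levels (flags are assigned, not simulated). Passing
tests therefore demonstrate correctness of the computations and their
detection power under idealized noise, not performance on real libraries.

## Known limitation: site recovery at the toy scale

With 50 boxcar sites of 500 bp on 1 Mb, the sites occupy ~2.5% of steps while
the calling budget is the top 1.5%, so the percentile cutoff necessarily
falls *inside* the site plateau; and a median window equal to the site width
depresses site edges (windows there mix site and background populations).
Each site's crossing run then averages ~300 bp with a wide spread, and the
200 bp length filter removes the unlucky tail: at ratio-noise sd 0.3 roughly
80–90% of planted sites are recovered while the precision of the calls stays
at ~100%. Recovery rises to essentially 100% with wider sites, lower noise,
or thresholding before smoothing; the pipeline keeps the smoothed-track
contract and reports recovery as measured.

## Problem sizes

Test and acceptance runs use a 1 Mb X analog (10^5 steps) for the
calling/distance chain, a 20 Mb autosome analog (2×10^6 steps) for the TSS
profile, 100 seeded replicates for the repeat-class estimator, and 100/50
random tracks of up to 2000/500 steps for the brute-force equivalence checks
— sizes at which the brute-force oracles are exact and the full suite runs in
seconds.
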