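# Methods

## Data model and coordinate conventions

All coordinates are 0-based half-open; GFF3 input (1-based inclusive) is
converted on read. BED is the native interval format. A probe's *position*
for every windowed computation is its interval midpoint,
`floor((start + end) / 2)` — tiling probes are short (default 50 bp)
relative to the windows (500–1000 bp), so the choice of anchor within the
probe is immaterial at the analysis scale, but fixing it makes all window
memberships exactly reproducible. A gene's TSS is the 5′ end of its model:
`start` on the plus strand, `end − 1` on the minus strand.

## Normalization chain

Raw two-channel intensities are processed as:

1. **Median scaling.** Each sample (channel) is multiplied by
   `500 / median(sample)`. This removes global labelling/hybridization
   intensity differences and makes the chain exactly invariant to
   per-sample scale factors.
2. **Quantile normalization, ChIP and input together.** All columns are
   forced onto the common rank-mean reference distribution (the
   across-column mean of sorted values at each rank). Ties receive the
   mean of the reference values over their rank span (mid-rank
   interpolation), making the result deterministic and invariant to input
   row order. The implementation agrees with `limma::normalizeQuantiles`
   to ~1e-12 (checked in the test suite by calling R).
3. **Log ratios.** Per replicate, `log2(chip / input)` element-wise.
4. **Window smoothing.** At each probe position *p*, the score is the
   mean of ratios at probe midpoints in `[p − w/2, p + w/2)` with
   `w = 500` bp; windows never cross chromosome boundaries; if fewer than
   4 defined ratios fall in the window the score is *missing* (NaN).
   The mean (rather than a median or trimmed mean) is used; the statistic
   is configurable in the API.
5. **Replicate combination.** Per-probe mean across replicates, ignoring
   missing values; a probe is missing only where all replicates are.
   Dye-swapped replicates need no special handling because channel roles
   (ChIP vs input) come from sample metadata, not dye.

Ratios are formed *after* joint quantile normalization. Placing the ratio
before quantile normalization would normalize ratio distributions rather
than channel distributions; normalizing "ChIP and input samples together"
only makes sense on channels, which fixes the order.

**Known bias.** Joint quantile normalization of ChIP and input channels
slightly compresses real enrichment and pushes background probes'
log-ratios marginally negative: enriched ChIP probes occupy the top ranks,
so the reference distribution's upper tail averages enriched ChIP values
with merely-high input values, and background ChIP probes are displaced
downward in rank. Both effects grow with the fraction of probes carrying
signal. At the simulator's default conditions (~1.7% of probes inside
enrichment domains, fly-like gene density) the recovered amplitude is
≈ 0.97× planted and the background median sits at ≈ −0.02 log2 units; the
parameter-recovery tests measure exactly this behaviour.

## Gene and interval scoring

* **TSS score:** mean of defined smoothed scores at probe midpoints in
  `[tss − 500, tss + 500)`; missing when fewer than 4 defined probes fall
  in the window. The window is symmetric (not strand-oriented): a ±500 bp
  window is its own mirror image, so orientation cannot change the score.
* **Interval calling:** maximal runs of probes with score strictly above
  the threshold (default 1.0 log2). Runs separated by ≤ 250 bp (end of
  one qualifying probe to start of the next) are merged; merged runs with
  fewer than 2 qualifying probes are dropped. The 250 bp merge gap is
  half the smoothing window and the 2-probe minimum suppresses
  single-probe noise; both are configurable. Each interval spans the
  first to last qualifying probe and is annotated with the mean score in
  a 1 kb window centred on `floor((start + end) / 2)`.
* **Metagene profiles:** probe offsets relative to the TSS, negated for
  minus-strand genes so negative is always upstream, pooled across genes
  into 50 bp bins over ±2 kb (span configurable); each bin reports the
  pooled-probe mean and the number of genes contributing ≥ 1 defined
  probe. Pooling probes (rather than averaging per-gene means) weights
  genes by their defined probe counts and is the natural estimator for an
  *accumulated* profile.
* **Random backgrounds:** the bin-wise average of metagene profiles over
  `n_samplings = 10` subsets of `n_genes = 942` genes drawn uniformly
  without replacement (within each sampling) from the gene universe;
  fully determined by the seed.

## Gene-set statistics

Set summaries report n (defined scores), median, quartiles by linear
interpolation, whiskers at the most extreme datum within 1.5×IQR of the
quartiles, and the linear fold enrichment `2^median`. Set-vs-reference
comparisons use a two-sided Welch (unequal-variance) t-test — the
conservative default when set sizes and spreads differ by orders of
magnitude; a pooled-variance test is available via `equal_var=True`.
P-values below 2.2e-16 are *displayed* as "< 2.2e-16" (the conventional
machine-precision floor) while the exact value is kept internally. If both
samples have zero variance the test is degenerate and p is reported as 1.0
or 0.0 by equality of means.

Between-condition ratios are `2^(median_A − median_B)` over genes defined
in both conditions, so reciprocal ratios multiply to exactly 1; per-gene
log2 differences are retained for top-k ranking (ties broken by gene id,
for determinism).

Gene sets can be defined from expression data: >k-fold down-regulation
(linear fold < 1/k, default k = 4) and presence in all tissues
(ubiquitous/housekeeping, default "present in every column").

## Chromatin-domain enrichment

Genes are assigned to five-state domain annotations either by TSS
containment (default) or by majority gene-body coverage (ties →
unassigned). Fold enrichment of a set over a universe is the ratio of
per-state fractions, with unassigned genes excluded from both
denominators; a state present in the set but absent from the universe is
flagged `+inf`. TSS containment is the default because promoter-proximal
state is what a TSS-window binding analysis interrogates; both rules are
exposed and results should name the rule used.

## Synthetic data generator

The generator emulates the features of a dense two-colour tiling design
that the pipeline actually exercises:

* probes tiled at fixed spacing (default 75 bp, length 50 bp) — a
  scaled-down whole-genome *Drosophila* design;
* default genome 2 × 9 Mb with 2000 non-overlapping genes (~9 kb/gene,
  the real fly gene density), placed one per slot with margins so planted
  domains never overlap;
* per-probe lognormal affinity (log2 sd 1.2, median 500) shared across
  channels — probe sequence effects dominate tiling-array intensity
  variance and span roughly two orders of magnitude;
* per-sample global scale factors (2^U(−0.5, 0.5)) and independent
  N(0, 0.3) log2 noise per probe per channel;
* ChIP channels additionally carry `2^signal`, where signal sums planted
  domain profiles — boxcar (default, width 1.5 kb) or Gaussian
  (sd = width/5) — of amplitude 1.5 log2 units centred on the TSSs of a
  10% target-gene fraction (200 targets);
* conditions with amplitude multipliers: "regulated" targets scale with
  the condition's multiplier while an optional "canonical" target class
  keeps full amplitude everywhere, mirroring a constitutive-vs-staged
  binding contrast;
* replicates (default 2) with a dye swap on even replicates.

All randomness flows from the single config seed; fixtures regenerate
byte-identically, and the ground truth (per-gene class and amplitude,
per-sample scales, config) is serialized beside the data.

**What it does not model:** probe GC/sequence bias beyond a static
affinity, spatial array artifacts, amplification bias, cell-mixture
effects, and correlated noise between neighbouring probes. The pipeline
contains no corrections for these, so passing recovery tests demonstrates
correctness of the implemented computations under the stated noise model,
not robustness to every artifact of real arrays.

## Numerical choices

* Missing scores are NaN and propagate: windows failing the minimum-oligo
  rule are missing, and all downstream means ignore missing values.
* Windowed means use per-chromosome prefix sums (O(n log n) with binary
  search); they agree with a brute-force O(n²) oracle to floating-point
  rounding (≤ ~1e-14 relative; summation order differs), with identical
  missing patterns.
* Quantile normalization interpolates mid-ranks linearly between adjacent
  reference order statistics.
* Quartiles interpolate linearly between order statistics (the numpy
  default), matching the boxplot convention used for the summaries.
* Degenerate inputs fail loudly with `ValidationError`: zero-length
  probes, duplicate identifiers, non-positive intensities, missing
  strands, unmatched ChIP samples, overlapping domain intervals.

## Problem sizes

The test suite and the acceptance script run on synthetic genomes of
18 Mb / 240k probes (default conditions) down to 0.3–3 Mb for focused
unit tests; brute-force oracle comparisons use randomized maps of up to a
few hundred probes, where O(n²) reference implementations stay fast.
These sizes give every statistic comfortable Monte-Carlo resolution while
keeping the whole suite in well under a minute.
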