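# Methods

## Model and workflow

ChIP-seq coverage at a base is modelled as enrichment plus background. The
control library measures background only, but at its own sequencing depth,
so the pipeline (i) estimates the background scaling between ChIP and
control, (ii) subtracts the scaled control, (iii) converts to reads per
million (RPM), (iv) aggregates over a group of uniform-width regions into a
mean or median profile with a bootstrap ribbon, and (v) compares profiles
with pseudometrics and permutation tests.

Coordinates are 0-based half-open throughout (BED-native); narrowPeak and
broadPeak are read with the same convention, dispatched on column count,
with the signalValue column stored as the region score. Region resizing
recenters each region to `[center − flank, center + flank)` with the center
taken as the floor of the midpoint; regions whose resized interval leaves
the chromosome are dropped rather than clamped, because the profile
arithmetic requires a rectangular matrix of one common width. Minus-strand
coverage vectors are reversed so every region reads 5'→3'; the operation is
an involution.

## Coverage semantics

Depth at a base counts mapped, primary, non-supplementary reads whose
aligned reference span covers it. Duplicates are retained by default (raw
coverage semantics; flags exist to exclude duplicates and QC-fail reads).
CIGAR M/=/X/D consume and cover the reference; N (reference skip) consumes
without covering — standard depth-of-coverage behaviour. An optional
`extend` replaces each read by a fixed-length interval from its 5' end, the
common fragment-extension practice; note that with extension, reads whose
*alignment* does not overlap a region are not fetched, so extension should
stay well below the flank. Per-region vectors are stored run-length
encoded; coverage is piecewise constant, so RLE is compact and expands
losslessly.

Replicates of one role are pooled by summing raw counts before any
normalisation (library sizes add), so one curve summarises a factor; a
per-replicate path is available by simply not pooling.

## NCIS background scaling

The fixed-bin variant: read 5' starts are counted in non-overlapping bins
(default 1000 bp — small enough to isolate peaks, large enough for stable
counts). For increasing threshold t over observed bin totals, the running
ratio r(t) = Σ chip / Σ control over bins with total ≤ t is tracked; r̂ is
taken at the first threshold where r stops decreasing *and* the
sub-threshold bins hold ≥ 75% of all non-empty bins. The intuition: as t
grows, bins are increasingly contaminated by enrichment, which only
inflates the ratio; the first non-decrease past the bulk of the genome
marks the background regime. If no threshold qualifies, the all-bins ratio
is used (logged). Both the bin size and the 75% fraction are exposed.

Subtraction is per region and per base: `max(0, chip − r̂·control)`,
clamped so coverage stays non-negative. Clamping makes the residual after
subtraction positively biased at low depth (E[max(0, X − r̂Y)] > 0 even
when E[X] = r̂·E[Y]); the residual fraction scales roughly as
0.4·√(var)/mean, i.e. ∝ 1/√depth. The synthetic checks of the noise-removal
effect therefore use deep background (~100× via fragment-length reads) so
the off-peak residual falls below 10% — at shallow real-world depths the
subtraction removes the background *in expectation* but per-base residual
noise remains proportionally larger. Experiments without a control skip
subtraction with a warning. RPM conversion (×10⁶ / library size) happens
last, with the pooled ChIP library size, so units stay interpretable.

## Profiles and bootstrap ribbons

Positions are binned (arithmetic mean per row; trailing partial bin dropped
with a warning) before bootstrapping, damping extreme single-base values.
The group profile is the column-wise mean or median (numpy median: midpoint
average for even counts). The ribbon is a *percentile* interval of the
bootstrap distribution: regions — the independent sampling units — are
resampled with replacement B times (default 1000, level 95%), the estimator
recomputed per resample, and per-position percentiles (α/2, 1 − α/2) taken.
The mean profile commutes exactly with binning; resampling is chunked (100
curves at a time) to bound memory. One seedable generator drives each
analysis; the seed is recorded in the output metadata. A single-region
matrix yields a zero-width ribbon with a warning rather than an error.

## Pseudometrics

All six take two equal-length non-negative curves. Validity thresholds
(defaults: minimum peak height 1 and minimum area 1, in curve units) guard
the ratio- and position-based metrics against extreme values from
near-empty curves; a guarded result is an explicit undefined value with a
reason, never NaN. Tied maxima use the median of the tied positions, which
is stable under symmetric plateaus and makes DIFF_POS_MAX antisymmetric.
RATIO_NORMALIZED_INTERSECT divides each curve by its own mean first, so it
is invariant to multiplying either curve by a positive constant — shape,
not amplitude. Spearman uses average ranks for ties and is undefined for
constant curves. Closed forms used in tests: for proportional curves p and
c·p, RATIO_INTERSECT = min(c,1)/max(c,1) and the normalised variant is 1.

The gradient/threshold rule: RATIO_INTERSECT between the moderate- and
high-activity profiles ≥ 0.85 ⇒ threshold (occupancy saturated before
maximal activity), else gradient; an undefined ratio is reported as
unclassifiable. The cutoff is a parameter.

## Permutation test

Pooled shuffle without replacement: all rows of both matrices are pooled,
reassigned to pseudo-groups of the original sizes, and the dissimilarity of
the two pseudo-profiles recomputed N times (default 1000). The pooled rows
are put in a canonical (lexicographic) order first, so the test is exactly
invariant to which group is passed first when group sizes are equal and the
metric is symmetric. p = (n_extreme + 1)/(N + 1) with ties counted as
extreme — the standard conservative Monte-Carlo correction; p is never 0.
Similarity-oriented metrics are adapted as 1 − value, and the adapter name
appears in reports. Rounds on which the metric is undefined are dropped
with a warning, reducing N. Multiple-testing correction across many factor
comparisons is left downstream (Benjamini–Hochberg recommended).

## Synthetic data generator

`generate_regions` places non-overlapping regions (spacing ≥ width)
uniformly at random via sorted uniform draws plus deterministic offsets,
with random strands. `simulate_experiment` writes coordinate-sorted,
indexed BAMs: ChIP = uniform Poisson background at rate c·λ per bp plus,
per region, Poisson(amplitude) peak reads whose 5' positions follow the
peak shape (Gaussian with width σ by default; flat and bimodal shapes
exercise the position- and intersect-based metrics), truncated to the
region; control = background at rate λ only. The true scaling c is what
NCIS should recover. Reads are single-end, error-free, uniquely mapped;
realized library sizes are recorded in the truth file.

Defaults emulate desk-scale study conditions: σ = 200 bp peaks, background
λ = 10⁻³ reads/bp, 50 bp reads. What the simulator deliberately omits:
read errors, mappability gaps, GC and chromatin-structure bias, duplicate
structure, paired ends. Passing tests therefore demonstrate the
*arithmetic and statistical* correctness of the pipeline, not robustness
to those real-data artefacts.

## Problem sizes in the checks

The quantitative checks use miniature genomes (≈1–2 Mb, ~5% peak content):
NCIS recovery and noise removal run on 30 regions of 4 kb with ~100×
background depth; ribbon calibration uses 500 simulated datasets of 200
regions at B = 200; permutation size uses 500 null datasets of 50 + 50
regions at N = 200. These sizes give Monte-Carlo error comfortably inside
the asserted bands while keeping runs desk-scale.

## Design choices and limitations

- Stratification by activity score: score 0 forms the "none" class; nonzero
  scores are ranked (stable in input order, so exact ties split with sizes
  differing by ≤ 1) and cut at configurable quantile edges, tertiles by
  default. Other cutpoint schemes can be expressed through the edges.
- Replicate pooling happens on counts before RPM; a pooling-after mode
  would weight replicates equally regardless of depth and is intentionally
  not the default.
- The fixed-bin NCIS variant is implemented; increasing-bin refinements are
  out of scope.
- The heatmap is a static export (TSV matrix + optional PNG, rows ordered
  by total coverage or input order); no interactive preview.
- BAM only (with BAI); CRAM, base-quality filtering and fragment
  reconstruction for paired ends are out of scope.
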