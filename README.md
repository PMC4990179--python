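# metaprofiler

Quantitative comparison of ChIP-seq enrichment profiles over groups of
genomic regions.

ChIP-seq surveys where a regulatory protein sits on the genome, but a single
locus is noisy: the informative picture is the *metagene* (aggregation)
profile — average coverage across hundreds of regions, plotted against
position relative to a common anchor such as the region center. Comparing
such profiles between region groups (e.g. promoters stratified by
transcriptional activity) or between experiments requires background
correction, normalisation and honest uncertainty estimates, not just
overlaying curves. `metaprofiler` provides that workflow end to end, for
anyone analysing occupancy of transcription factors, cofactors or histone
marks at regulatory elements.

## What it computes

Given coordinate-sorted, indexed BAM files, region files (BED,
narrowPeak/broadPeak) and a design sheet assigning each BAM a role (ChIP,
control, unused) per experiment:

1. **Coverage.** Per-region read depth, stored run-length encoded, for the
   regions of interest only; minus-strand regions can be flipped to 5'→3'.
2. **Background correction (NCIS).** The control must be rescaled before
   subtraction: low-total genome bins are background in both samples, and
   the ratio of ChIP to control counts over those bins estimates the
   scaling r̂. The corrected coverage is max(0, chip − r̂·control).
3. **Normalisation.** Reads per million aligned (RPM), so libraries of
   different depth are comparable.
4. **Profiles and ribbons.** Column-wise mean or median over the regions ×
   positions matrix (binned to damp extreme single-base values), with a
   bootstrap percentile ribbon: regions are resampled with replacement
   (B = 1000 by default) and the ribbon spans the central 95% of the
   resampled estimator at each position.
5. **Comparison.** Six profile-similarity pseudometrics (RATIO_AREA,
   DIFF_POS_MAX, RATIO_MAX_MAX, RATIO_INTERSECT, RATIO_NORMALIZED_INTERSECT,
   SPEARMAN_CORRELATION), each guarded by editable validity thresholds, and
   a permutation test: pool the regions of two groups, reshuffle into
   pseudo-groups, and compute p = (n_extreme + 1)/(N + 1) for any
   dissimilarity metric.
6. **Classification.** RATIO_INTERSECT — area under the pointwise minimum
   of two profiles over the area under their pointwise maximum — between
   the moderate- and high-activity group distinguishes a *gradient* effect
   (occupancy tracks activity, ratio < 0.85) from a *threshold* effect
   (occupancy saturates early, ratio ≥ 0.85).

A seeded simulator (`metaprofiler.synthetic`) generates BAM + BED + design
fixtures with known peak amplitudes and background scaling, so the whole
pipeline is testable without downloads.

## Worked example

Simulate a small dataset (30 regions with Gaussian peaks, uniform
background, a control at half the ChIP background rate — true scaling 2)
and run the pipeline:

```sh
metaprofiler simulate --n-regions 30 --width 2000 --n-chrom 1 \
    --chrom-length 1000000 --amplitude 30 --background-rate 0.002 \
    --control-scale 2 --seed 5 --out demo
metaprofiler run --regions demo/regions.bed --design demo/design.tsv \
    --chrom-sizes demo/chrom.sizes --flank 1000 --bin-size 20 \
    --bootstrap 200 --seed 5 --out demo/out
```

The run logs the estimated background scaling

```
experiment exp1: NCIS r_hat = 2.0889
```

— close to the true value of 2 — and writes `demo/out_profiles.tsv`:

```
experiment  group    position  value        ci_low       ci_high
exp1        regions  -1000     28.51583468  6.659286098  55.36265432
exp1        regions  -980      18.45142244  3.992216855  36.29898014
...
```

The curve peaks in the bin at position −20 (the 20 bp bin covering the
region center) at 630.7 RPM with a 95% bootstrap ribbon of [503.0, 765.3]:
the simulated enrichment is centered as constructed, background-corrected
coverage is in reads per million, and the ribbon quantifies how much the
mean profile would vary under resampling of regions. `demo/out_metagene.png`
shows the curve with its translucent ribbon, and `demo/out_metadata.yaml`
records every setting, seed and the estimated r̂, sufficient to reproduce
the run exactly.

To compare two groups, pass two region files and request permutation tests
(`--permutations 1000`); the report lists the observed
1 − RATIO_INTERSECT dissimilarity and its permutation p-value per group
pair.

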