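"""Background scaling (NCIS), background subtraction and RPM conversion.

ChIP-seq signal mixes true enrichment with background noise. The matched
control measures background only, but at a different sequencing depth, so it
must be rescaled before subtraction. The NCIS (Normalization of ChIP-Seq)
idea: bins of the genome with low total read count are background in both
samples, and the ratio of ChIP to control counts restricted to those bins
estimates the background scaling factor r. Subtracting ``r * control`` from
the ChIP coverage then removes the noise component while leaving enrichment.

The fixed-bin NCIS variant is implemented: non-overlapping bins of a single
width (default 1000 bp), read 5' starts counted per bin, and the threshold
on bin totals grown until the running ratio first stops decreasing AND the
bins below the threshold hold at least 75% of all non-empty bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pysam

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseRatio:
    """Estimated control-to-ChIP background scaling factor."""

    r_hat: float
    bin_size: int
    background_fraction: float  # fraction of non-empty bins used in the estimate

    def __post_init__(self) -> None:
        if not self.r_hat > 0:
            raise ValueError("r_hat must be > 0")
        if not (0 < self.background_fraction <= 1):
            raise ValueError("background_fraction must be in (0, 1]")


def bin_genome_counts(path, chrom_sizes: Mapping[str, int], bin_size: int) -> np.ndarray:
    """Count read 5'-start positions per fixed-width genome bin.

    Returns one concatenated vector over all chromosomes in ``chrom_sizes``
    order (chromosomes absent from the BAM contribute zero bins).
    """
    if bin_size < 100:
        raise ValueError("bin_size must be >= 100 bp")
    chunks = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        contigs = set(bam.references)
        for chrom, length in chrom_sizes.items():
            n_bins = -(-length // bin_size)
            if chrom not in contigs:
                chunks.append(np.zeros(n_bins, dtype=np.int64))
                continue
            starts = [
                read.reference_start
                for read in bam.fetch(chrom)
                if not (read.is_unmapped or read.is_secondary or read.is_supplementary)
            ]
            counts = np.bincount(
                np.asarray(starts, dtype=np.int64) // bin_size, minlength=n_bins
            )[:n_bins]
            chunks.append(counts)
    return np.concatenate(chunks)


def ncis_ratio(
    chip,
    control,
    bin_size: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
    background_quantile: float = 0.75,
) -> NoiseRatio:
    """Estimate the ChIP/control background scaling factor r_hat.

    ``chip`` and ``control`` are either BAM paths (then ``chrom_sizes`` is
    required) or pre-binned count vectors of equal length. For increasing
    threshold t over observed bin totals t_i = chip_i + control_i, the running
    ratio r(t) = sum(chip_i | t_i <= t) / sum(control_i | t_i <= t) is
    tracked; r_hat is r at the smallest t where r first fails to decrease and
    the sub-threshold bins comprise at least ``background_quantile`` of the
    non-empty bins. If no threshold qualifies, the ratio over all bins is
    returned.
    """
    if not isinstance(chip, np.ndarray):
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required when passing BAM paths")
        chip = bin_genome_counts(chip, chrom_sizes, bin_size)
        control = bin_genome_counts(control, chrom_sizes, bin_size)
    chip = np.asarray(chip, dtype=np.float64)
    control = np.asarray(control, dtype=np.float64)
    if chip.shape != control.shape:
        raise ValueError("chip and control bin vectors differ in length")

    totals = chip + control
    n_nonempty = int((totals > 0).sum())
    if n_nonempty == 0:
        raise ValueError("cannot estimate ratio: all bins are empty")
    order = np.argsort(totals, kind="stable")
    t_sorted = totals[order]
    cum_chip = np.cumsum(chip[order])
    cum_ctrl = np.cumsum(control[order])
    cum_nonempty = np.cumsum(t_sorted > 0)

    # last index of each distinct total = candidate threshold
    last = np.flatnonzero(np.diff(t_sorted, append=np.inf) != 0)
    r_prev = None
    chosen = None
    for k in last:
        if cum_ctrl[k] == 0:
            continue  # ratio undefined below this threshold
        r_k = cum_chip[k] / cum_ctrl[k]
        frac = cum_nonempty[k] / n_nonempty
        if (
            r_prev is not None
            and r_k >= r_prev
            and frac >= background_quantile
        ):
            chosen = (r_k, frac)
            break
        r_prev = r_k
    if chosen is None:
        if cum_ctrl[-1] == 0:
            raise ValueError("cannot estimate ratio: control has zero counts everywhere")
        chosen = (cum_chip[-1] / cum_ctrl[-1], 1.0)
        log.info("ncis_ratio: no qualifying threshold; using the all-bins ratio")
    r_hat, frac = chosen
    if r_hat <= 0:
        raise ValueError("cannot estimate ratio: ChIP background counts are zero")
    return NoiseRatio(r_hat=float(r_hat), bin_size=int(bin_size), background_fraction=float(frac))


def subtract_background(
    chip_cov: np.ndarray, control_cov: np.ndarray, r: NoiseRatio | float
) -> np.ndarray:
    """Remove scaled control coverage from ChIP coverage, clamped at zero."""
    chip_cov = np.asarray(chip_cov, dtype=np.float64)
    control_cov = np.asarray(control_cov, dtype=np.float64)
    if chip_cov.shape != control_cov.shape:
        raise ValueError("chip and control coverage vectors differ in shape")
    r_hat = r.r_hat if isinstance(r, NoiseRatio) else float(r)
    return np.maximum(0.0, chip_cov - r_hat * control_cov)


def rpm_normalize(cov: np.ndarray, library_size: int) -> np.ndarray:
    """Convert raw depth to reads per million aligned."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0 for RPM normalisation")
    return np.asarray(cov, dtype=np.float64) * (1e6 / library_size)


def write_bedgraph(
    counts: np.ndarray, chrom_sizes: Mapping[str, int], bin_size: int, path
) -> None:
    """Audit export of binned genome counts as BEDGRAPH."""
    with open(path, "w") as fh:
        i = 0
        for chrom, length in chrom_sizes.items():
            n_bins = -(-length // bin_size)
            for b in range(n_bins):
                v = counts[i + b]
                if v:
                    start = b * bin_size
                    fh.write(f"{chrom}\t{start}\t{min(start + bin_size, length)}\t{v:g}\n")
            i += n_bins
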