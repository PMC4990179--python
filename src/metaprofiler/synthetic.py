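"""Seeded simulator of region files and alignment files with known truth.

Emulates the canonical ChIP + matched-control structure: every region
carries an enrichment peak of group-dependent expected read count whose 5'
positions follow a configurable shape around the region center (Gaussian by
default), on top of uniform Poisson background; the control has the
background only, at a rate differing from the ChIP background by a known
scaling factor. Reads are single-end, error-free and uniquely mapped —
alignment fidelity is not what these fixtures test. All randomness flows
from one seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pysam
import yaml

from .regions import GenomicRegion, RegionGroup

PEAK_SHAPES = ("gaussian", "flat", "bimodal")


@dataclass
class SimulationTruth:
    """Generative parameters, plus realized library sizes after simulation."""

    amplitudes: dict[str, float]  # expected peak reads per region, per group label
    sigma: float = 200.0  # peak width (bp) of 5'-position spread
    background_rate: float = 1e-3  # control background, reads per bp genome-wide
    control_scale: float = 1.0  # ChIP background = control_scale * background_rate
    read_length: int = 50
    shape: str = "gaussian"
    seed: int = 0
    chip_library_size: int | None = None  # realized counts, set by simulate_experiment
    control_library_size: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.background_rate < 0 or self.control_scale <= 0:
            raise ValueError("rates must be non-negative, control_scale > 0")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be >= 0")
        if self.shape not in PEAK_SHAPES:
            raise ValueError(f"shape must be one of {PEAK_SHAPES}")


def generate_regions(
    n: int,
    width: int,
    n_chrom: int = 1,
    chrom_length: int = 10_000_000,
    seed: int | None = None,
    label: str = "synthetic",
) -> tuple[RegionGroup, dict[str, int]]:
    """Place n non-overlapping regions of ``width`` bp, >= width apart.

    Regions are spread across ``n_chrom`` chromosomes of ``chrom_length`` bp
    each, positioned uniformly at random subject to the spacing constraint
    (sorted uniform draws plus deterministic offsets), strands assigned at
    random. Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    per_chrom = np.full(n_chrom, n // n_chrom)
    per_chrom[: n % n_chrom] += 1
    regions: list[GenomicRegion] = []
    for chrom, n_i in zip(chrom_sizes, per_chrom):
        if n_i == 0:
            continue
        slack = chrom_length - 2 * width * int(n_i)
        if slack < 0:
            raise ValueError(
                f"cannot fit {n_i} regions of width {width} (+ spacing) into {chrom_length} bp"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=int(n_i)))
        starts = offsets + 2 * width * np.arange(int(n_i))
        for s in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            regions.append(
                GenomicRegion(
                    chrom, int(s), int(s) + width,
                    name=f"region_{len(regions) + 1}", score=None, strand=strand,
                )
            )
    return RegionGroup(label=label, regions=regions), chrom_sizes


def _peak_positions(rng, region: GenomicRegion, n: int, truth: SimulationTruth) -> np.ndarray:
    c = region.center
    if truth.shape == "gaussian":
        pos = rng.normal(c, truth.sigma, size=n)
    elif truth.shape == "flat":
        pos = rng.uniform(region.start, region.end, size=n)
    else:  # bimodal: two modes flanking the center
        side = rng.random(n) < 0.5
        mode = np.where(side, c - 2 * truth.sigma, c + 2 * truth.sigma)
        pos = rng.normal(mode, truth.sigma / 2)
    hi = max(region.start, region.end - truth.read_length)
    return np.clip(np.round(pos), region.start, hi).astype(np.int64)


def _write_bam(path, reads, chrom_sizes, read_length: int) -> None:
    """Write (chrom, start) tuples as a coordinate-sorted, indexed BAM."""
    chroms = list(chrom_sizes)
    tid = {c: i for i, c in enumerate(chroms)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    reads = sorted(reads, key=lambda r: (tid[r[0]], r[1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (chrom, start) in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"read_{i}"
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            a.reference_id = tid[chrom]
            a.reference_start = int(start)
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.flag = 0
            bam.write(a)
    pysam.index(str(path))


def _background_reads(rng, chrom_sizes, rate: float, read_length: int) -> list:
    reads = []
    for chrom, length in chrom_sizes.items():
        span = max(1, length - read_length)
        n = rng.poisson(rate * span)
        starts = rng.integers(0, span, size=n)
        reads.extend((chrom, int(s)) for s in starts)
    return reads


def simulate_experiment(
    groups: list[RegionGroup] | RegionGroup,
    chrom_sizes: dict[str, int],
    truth: SimulationTruth,
    outdir,
    prefix: str = "sim",
) -> tuple[Path, Path, SimulationTruth]:
    """Write a ChIP BAM, a control BAM and the truth file.

    ChIP reads = uniform Poisson background at rate control_scale *
    background_rate plus, per region, Poisson(amplitude[group]) peak reads
    with 5' positions drawn from the peak shape and truncated to the region.
    Control reads = background at ``background_rate`` only. Both BAMs are
    coordinate-sorted and indexed; realized library sizes are recorded in
    the returned truth and in ``<prefix>_truth.yaml``.
    """
    if isinstance(groups, RegionGroup):
        groups = [groups]
    missing = [g.label for g in groups if g.label not in truth.amplitudes]
    if missing:
        raise ValueError(f"no amplitude specified for groups: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)

    chip_reads = _background_reads(
        rng, chrom_sizes, truth.control_scale * truth.background_rate, truth.read_length
    )
    for group in groups:
        amp = truth.amplitudes[group.label]
        for region in group:
            n_peak = rng.poisson(amp)
            for p in _peak_positions(rng, region, n_peak, truth):
                chip_reads.append((region.chrom, int(p)))
    control_reads = _background_reads(rng, chrom_sizes, truth.background_rate, truth.read_length)

    chip_path = outdir / f"{prefix}_chip.bam"
    control_path = outdir / f"{prefix}_control.bam"
    _write_bam(chip_path, chip_reads, chrom_sizes, truth.read_length)
    _write_bam(control_path, control_reads, chrom_sizes, truth.read_length)

    truth.chip_library_size = len(chip_reads)
    truth.control_library_size = len(control_reads)
    with open(outdir / f"{prefix}_truth.yaml", "w") as fh:
        yaml.safe_dump(asdict(truth), fh, sort_keys=False)
    return chip_path, control_path, truth
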