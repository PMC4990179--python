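"""Per-region read coverage from BAM files, stored run-length encoded.

Coverage is only materialised for the regions under study: each region's
depth vector is compressed to run-length form (coverage is piecewise
constant, so RLE is compact) and expanded lazily. Depth at a base is the
number of selected reads whose aligned reference span covers it. By default
the selected reads are mapped primary records, duplicates included; deletions
(CIGAR ``D``) are covered, reference skips (``N``) are not — standard
depth-of-coverage semantics for ChIP-seq.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

from .regions import RegionGroup

log = logging.getLogger(__name__)

# CIGAR operations that consume the reference
_REF_CONSUME = {0, 2, 3, 7, 8}  # M, D, N, =, X
# of those, the ones that count as covered
_REF_COVER = {0, 2, 7, 8}  # M, D, =, X


@dataclass(frozen=True)
class RLEVector:
    """Run-length encoded non-negative integer/real vector."""

    values: np.ndarray
    lengths: np.ndarray

    @classmethod
    def encode(cls, dense: np.ndarray) -> "RLEVector":
        dense = np.asarray(dense)
        if dense.size == 0:
            return cls(np.array([]), np.array([], dtype=np.int64))
        change = np.flatnonzero(dense[1:] != dense[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [dense.size]))
        return cls(dense[starts].copy(), (ends - starts).astype(np.int64))

    def expand(self) -> np.ndarray:
        return np.repeat(self.values, self.lengths)

    def __len__(self) -> int:
        return int(self.lengths.sum())


@dataclass
class CoverageTrack:
    """Per-region coverage for one sample over one region group."""

    sample_id: str
    vectors: list[RLEVector] = field(default_factory=list)
    library_size: int = 0

    def dense(self, i: int) -> np.ndarray:
        return self.vectors[i].expand()

    def to_matrix(self) -> np.ndarray:
        """Stack the per-region vectors into a (regions x positions) array."""
        if not self.vectors:
            return np.zeros((0, 0))
        return np.vstack([v.expand() for v in self.vectors]).astype(float)


def _select(read, include_duplicates: bool, include_qcfail: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if not include_duplicates and read.is_duplicate:
        return False
    if not include_qcfail and read.is_qcfail:
        return False
    return True


def library_size(
    path, include_duplicates: bool = True, include_qcfail: bool = True
) -> int:
    """Number of aligned (mapped, primary, non-supplementary) records.

    Used as the denominator of reads-per-million normalisation.
    """
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{path} has no index; create one with 'samtools index {path}'"
            )
        n = sum(
            1
            for read in bam.fetch(until_eof=True)
            if _select(read, include_duplicates, include_qcfail)
        )
    if n == 0:
        raise ValueError(f"{path} has no aligned reads; RPM normalisation is undefined")
    return n


def _read_spans(read, extend: int | None):
    """Reference intervals covered by one read (half-open).

    With ``extend``, the read is replaced by an ``extend``-bp interval from
    its 5' end (fragment-length extension). Otherwise the CIGAR is walked:
    M/=/X/D consume and cover the reference, N consumes without covering.
    """
    if extend is not None:
        if read.is_reverse:
            return [(read.reference_end - extend, read.reference_end)]
        return [(read.reference_start, read.reference_start + extend)]
    spans = []
    pos = read.reference_start
    run_start = pos
    in_run = False
    for op, length in read.cigartuples:
        if op not in _REF_CONSUME:
            continue
        if op in _REF_COVER:
            if not in_run:
                run_start, in_run = pos, True
            pos += length
        else:  # N: close any open run
            if in_run:
                spans.append((run_start, pos))
                in_run = False
            pos += length
    if in_run:
        spans.append((run_start, pos))
    return spans


def region_coverage(
    path,
    group: RegionGroup,
    extend: int | None = None,
    include_duplicates: bool = True,
    include_qcfail: bool = True,
    sample_id: str | None = None,
) -> CoverageTrack:
    """Extract per-region depth vectors for every region in ``group``.

    Regions are expected to be resized to a uniform width. Reads partially
    overlapping a region contribute over the overlap only. Regions on
    chromosomes absent from the BAM header yield zero vectors with a warning.
    """
    width = group.width
    if width is None:
        raise ValueError(f"group {group.label!r} does not have uniform width")
    track = CoverageTrack(sample_id=sample_id or str(path))
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{path} has no index; create one with 'samtools index {path}'"
            )
        contigs = set(bam.references)
        track.library_size = sum(
            1
            for read in bam.fetch(until_eof=True)
            if _select(read, include_duplicates, include_qcfail)
        )
        for region in group:
            dense = np.zeros(width, dtype=np.int64)
            if region.chrom not in contigs:
                log.warning(
                    "chromosome %s absent from %s; zero coverage for %s",
                    region.chrom, path, region.name,
                )
                track.vectors.append(RLEVector.encode(dense))
                continue
            for read in bam.fetch(region.chrom, region.start, region.end):
                if not _select(read, include_duplicates, include_qcfail):
                    continue
                for s, e in _read_spans(read, extend):
                    lo = max(s, region.start) - region.start
                    hi = min(e, region.end) - region.start
                    if hi > lo:
                        dense[lo:hi] += 1
            track.vectors.append(RLEVector.encode(dense))
    return track
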