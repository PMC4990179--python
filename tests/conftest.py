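import numpy as np
import pysam
import pytest

from metaprofiler.regions import GenomicRegion, RegionGroup


@pytest.fixture
def make_bam(tmp_path):
    """Factory writing a coordinate-sorted, indexed BAM from read tuples.

    Each read is (chrom, start, cigar) or (chrom, start, cigar, flag).
    """

    counter = {"n": 0}

    def _make(reads, chrom_sizes, name=None):
        counter["n"] += 1
        path = tmp_path / (name or f"reads_{counter['n']}.bam")
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
        }
        tid = {c: i for i, c in enumerate(chrom_sizes)}
        normalized = []
        for r in reads:
            chrom, start, cigar = r[0], r[1], r[2]
            flag = r[3] if len(r) > 3 else 0
            normalized.append((tid[chrom], start, cigar, flag, chrom))
        normalized.sort(key=lambda r: (r[0], r[1]))
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for i, (t, start, cigar, flag, chrom) in enumerate(normalized):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"r{i}"
                a.flag = flag
                a.reference_id = t
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = cigar
                qlen = a.infer_query_length() or 10
                a.query_sequence = "A" * qlen
                a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
                bam.write(a)
        pysam.index(str(path))
        return path

    return _make


@pytest.fixture
def simple_group():
    return RegionGroup(
        "g",
        [
            GenomicRegion("chr1", 100, 200, "r1", strand="+"),
            GenomicRegion("chr1", 400, 500, "r2", strand="-"),
        ],
    )


def brute_force_coverage(reads, region):
    """Oracle: per-base depth of a region from explicit read spans.

    ``reads`` are (chrom, start, end) reference spans.
    """
    dense = np.zeros(region.end - region.start, dtype=int)
    for chrom, s, e in reads:
        if chrom != region.chrom:
            continue
        lo, hi = max(s, region.start), min(e, region.end)
        for p in range(lo, hi):
            dense[p - region.start] += 1
    return dense
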