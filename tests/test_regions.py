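import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaprofiler.regions import (
    GenomicRegion,
    RegionFileError,
    RegionGroup,
    orient_region_coverage,
    read_bed,
    read_narrowpeak,
    resize_regions,
    stratify_by_score,
    write_bed,
)


def _write(tmp_path, text, name="regions.bed"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadBed:
    def test_six_column_line_maps_fields(self, tmp_path):
        g = read_bed(_write(tmp_path, "chr1\t100\t200\tr1\t0\t+\n"))
        (r,) = g.regions
        assert (r.chrom, r.start, r.end, r.name, r.strand) == ("chr1", 100, 200, "r1", "+")

    def test_empty_file_gives_empty_group(self, tmp_path):
        assert len(read_bed(_write(tmp_path, ""))) == 0

    @pytest.mark.parametrize(
        "line",
        ["chr1\t300\t200", "chr1\tx\t200", "chr1\t100"],
        ids=["inverted", "non-integer", "too-few-fields"],
    )
    def test_malformed_line_reports_line_number(self, tmp_path, line):
        with pytest.raises(RegionFileError, match="line 1"):
            read_bed(_write(tmp_path, line + "\n"))

    def test_missing_name_and_strand_defaults(self, tmp_path):
        g = read_bed(_write(tmp_path, "chr1\t0\t10\nchr2\t5\t15\n"))
        assert g[0].name == "region_1" and g[1].name == "region_2"
        assert g[0].strand == "."

    def test_round_trip_preserves_coordinates_and_strand(self, tmp_path):
        g = RegionGroup(
            "g",
            [
                GenomicRegion("chr1", 10, 50, "a", score=3.5, strand="-"),
                GenomicRegion("chr2", 0, 7, "b", score=0, strand="+"),
            ],
        )
        out = tmp_path / "out.bed"
        write_bed(g, out)
        back = read_bed(out)
        for orig, rt in zip(g, back):
            assert (orig.chrom, orig.start, orig.end, orig.name, orig.strand) == (
                rt.chrom, rt.start, rt.end, rt.name, rt.strand,
            )


class TestReadNarrowPeak:
    NP = "chr1\t100\t500\tpeak1\t300\t.\t7.5\t10.2\t8.1\t200\n"
    BP = "chr1\t100\t500\tpeak1\t300\t+\t4.5\t10.2\t8.1\n"

    def test_narrowpeak_signal_value_in_score(self, tmp_path):
        g = read_narrowpeak(_write(tmp_path, self.NP, "a.narrowPeak"))
        assert g[0].score == 7.5

    def test_broadpeak_dispatch_on_column_count(self, tmp_path):
        g = read_narrowpeak(_write(tmp_path, self.BP, "a.broadPeak"))
        assert g[0].score == 4.5 and g[0].strand == "+"

    def test_wrong_column_count_rejected(self, tmp_path):
        with pytest.raises(RegionFileError, match="columns"):
            read_narrowpeak(_write(tmp_path, "chr1\t1\t2\tn\t0\t.\t1\t1\n"))


class TestResize:
    SIZES = {"chr1": 100_000}

    def test_recenters_to_twice_flank(self):
        g = RegionGroup("g", [GenomicRegion("chr1", 5000, 5100)])
        out = resize_regions(g, 1000, self.SIZES)
        assert (out[0].start, out[0].end) == (4050, 6050)

    def test_out_of_bounds_region_dropped(self):
        g = RegionGroup(
            "g",
            [GenomicRegion("chr1", 100, 200), GenomicRegion("chr1", 5000, 5100)],
        )
        out = resize_regions(g, 1000, self.SIZES)
        assert len(out) == 1 and out[0].start == 4050

    def test_all_dropped_is_an_error(self):
        g = RegionGroup("g", [GenomicRegion("chr1", 100, 200)])
        with pytest.raises(ValueError, match="no regions remain"):
            resize_regions(g, 1000, self.SIZES)

    def test_uniform_width_and_count_never_increases(self):
        rng = np.random.default_rng(0)
        regions = [
            GenomicRegion("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 90_000, 50), rng.integers(50, 5000, 50))
        ]
        g = RegionGroup("g", regions)
        out = resize_regions(g, 750, self.SIZES)
        assert out.width == 1500
        assert len(out) <= len(g)

    def test_already_centered_region_keeps_width(self):
        g = RegionGroup("g", [GenomicRegion("chr1", 2000, 2000 + 2 * 600)])
        out = resize_regions(g, 600, self.SIZES)
        assert out[0].width == 1200 and out[0].start == 2000


class TestOrient:
    def test_minus_reversed_plus_identity(self):
        v = np.array([1, 2, 3])
        assert orient_region_coverage(v, "-").tolist() == [3, 2, 1]
        assert orient_region_coverage(v, "+").tolist() == [1, 2, 3]
        assert orient_region_coverage(v, ".").tolist() == [1, 2, 3]

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=50))
    def test_involution(self, values):
        v = np.array(values)
        twice = orient_region_coverage(orient_region_coverage(v, "-"), "-")
        assert twice.tolist() == values


def _scored_group(scores):
    return RegionGroup(
        "g",
        [
            GenomicRegion("chr1", 100 * i + 10, 100 * i + 60, f"r{i}", score=s)
            for i, s in enumerate(scores)
        ],
    )


class TestStratify:
    def test_tertile_boundaries(self):
        out = stratify_by_score(_scored_group([0, 0, 1, 2, 3, 4, 5, 6]))
        assert [r.score for r in out["none"]] == [0, 0]
        assert [r.score for r in out["low"]] == [1, 2]
        assert [r.score for r in out["moderate"]] == [3, 4]
        assert [r.score for r in out["high"]] == [5, 6]

    def test_three_distinct_nonzero_one_per_class(self):
        out = stratify_by_score(_scored_group([0, 0, 5, 1, 9]))
        assert [len(out[k]) for k in ("low", "moderate", "high")] == [1, 1, 1]
        assert out["low"][0].score == 1 and out["high"][0].score == 9

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_all_ties_split_evenly(self, n):
        out = stratify_by_score(_scored_group([2.0] * n))
        sizes = [len(out[k]) for k in ("low", "moderate", "high")]
        assert sum(sizes) == n and max(sizes) - min(sizes) <= 1

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            stratify_by_score(_scored_group([0, 0, 1, 2]))

    @given(
        st.lists(st.floats(0, 100, allow_nan=False, width=32), min_size=5, max_size=60)
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_is_disjoint_and_exhaustive(self, scores):
        if sum(1 for s in scores if s > 0) < 3:
            return
        g = _scored_group(scores)
        out = stratify_by_score(g)
        names = [r.name for grp in out.values() for r in grp]
        assert sorted(names) == sorted(r.name for r in g)
        assert len(set(names)) == len(names)
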