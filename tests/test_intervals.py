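import io

import pytest
from hypothesis import given, strategies as st

from acgh.intervals import (
    GenomeBuild,
    GenomicInterval,
    merge_intervals,
    overlaps,
    read_bed,
    span,
    write_bed,
)

# the eight recurrent chr13 events from the published large-event table
CHR13_EVENTS = [
    (48_998_999, 49_016_999),
    (48_992_999, 49_010_999),
    (48_991_360, 49_017_997),
    (48_991_360, 49_017_997),
    (48_991_360, 49_017_997),
    (48_993_325, 49_013_328),
    (48_991_360, 49_017_997),
    (48_992_999, 49_010_999),
]


def ivs(chrom="chr1"):
    return st.builds(
        lambda s, l: GenomicInterval(chrom, s, s + l),
        st.integers(0, 10_000),
        st.integers(1, 500),
    )


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end,expected",
        [
            ("chr25", 32_362_844, 32_470_747, 107_903),
            ("chr13", 48_998_999, 49_016_999, 18_000),
            ("chr1", 5, 6, 1),
        ],
    )
    def test_span_matches_length_column(self, chrom, start, end, expected):
        assert span(GenomicInterval(chrom, start, end)) == expected

    @pytest.mark.parametrize("start,end", [(10, 10), (10, 5), (-1, 5)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_bounds_checked_against_build(self, toy_build):
        GenomicInterval("chr1", 0, 240_000).validate_against(toy_build)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 240_001).validate_against(toy_build)
        with pytest.raises(ValueError):
            GenomicInterval("chr99", 0, 10).validate_against(toy_build)


class TestOverlaps:
    def test_published_rows_overlap(self):
        a = GenomicInterval("chr3", 1_020_294, 1_039_699)
        b = GenomicInterval("chr3", 1_020_294, 1_042_839)
        assert overlaps(a, b)

    def test_abutting_halfopen_do_not_overlap(self):
        assert not overlaps(
            GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)
        )

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(
            GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)
        )

    def test_max_gap_bridges_nearby_intervals(self):
        a = GenomicInterval("chr1", 0, 10)
        b = GenomicInterval("chr1", 15, 25)
        assert not overlaps(a, b)
        assert overlaps(a, b, max_gap=5)

    @given(ivs(), ivs())
    def test_symmetric(self, a, b):
        assert overlaps(a, b) == overlaps(b, a)

    @given(ivs())
    def test_reflexive(self, a):
        assert overlaps(a, a)


def brute_force_union(intervals):
    """Oracle: mark covered bases one by one."""
    covered = {}
    for iv in intervals:
        covered.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    out = []
    for chrom in sorted(covered):
        positions = sorted(covered[chrom])
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append(GenomicInterval(chrom, start, prev + 1))
                start = p
            prev = p
        out.append(GenomicInterval(chrom, start, prev + 1))
    return out


class TestMerge:
    def test_recurrent_chr13_events_merge_to_one_locus(self):
        intervals = [GenomicInterval("chr13", s, e) for s, e in CHR13_EVENTS]
        offset = 48_990_000  # brute-force oracle on offset coordinates
        small = [
            GenomicInterval("chr13", s - offset, e - offset) for s, e in CHR13_EVENTS
        ]
        expected = [
            GenomicInterval(iv.chrom, iv.start + offset, iv.end + offset)
            for iv in brute_force_union(small)
        ]
        merged = merge_intervals(intervals)
        assert merged == expected
        assert merged == [GenomicInterval("chr13", 48_991_360, 49_017_997)]

    def test_hand_computed_union(self):
        got = merge_intervals(
            [
                GenomicInterval("c", 0, 10),
                GenomicInterval("c", 5, 20),
                GenomicInterval("c", 30, 40),
            ]
        )
        assert got == [GenomicInterval("c", 0, 20), GenomicInterval("c", 30, 40)]

    def test_disjoint_inputs_unchanged(self):
        items = [GenomicInterval("c", 0, 5), GenomicInterval("c", 10, 15)]
        assert merge_intervals(items) == items

    def test_empty(self):
        assert merge_intervals([]) == []

    @given(st.lists(ivs(), max_size=15))
    def test_matches_brute_force_and_is_idempotent(self, intervals):
        merged = merge_intervals(intervals)
        if intervals:
            assert merged == brute_force_union(intervals)
        assert merge_intervals(merged) == merged
        # disjoint and sorted
        for a, b in zip(merged, merged[1:]):
            assert (a.chrom, a.end) <= (b.chrom, b.start) or a.chrom < b.chrom
        if merged:
            assert max(m.span for m in merged) >= max(
                (iv.span for iv in intervals), default=0
            )


class TestIO:
    def test_bed_round_trip(self):
        records = [
            (GenomicInterval("chr1", 0, 100), "Self1", 517.0),
            (GenomicInterval("chrU", 50, 75), "Low3", 744.0),
        ]
        buf = io.StringIO()
        write_bed(records, buf)
        buf.seek(0)
        assert read_bed(buf) == records

    def test_chrom_sizes_round_trip(self, tmp_path, toy_build):
        path = tmp_path / "toy.chrom.sizes"
        toy_build.to_chrom_sizes(path)
        again = GenomeBuild.from_chrom_sizes(path, name="toy")
        assert again == toy_build

    def test_build_invariants(self):
        with pytest.raises(ValueError):
            GenomeBuild("x", (("chr1", 10), ("chr1", 20)))
        with pytest.raises(ValueError):
            GenomeBuild("x", (("chr1", 0),))
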