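"""Interval-core behaviour checked against per-base bitmap oracles."""

import numpy as np
import pytest

from vdrcohort.genome import (
    GenomeLayout,
    SegmentTrack,
    merge_union,
    midpoints,
    overlap_bp,
    overlap_count,
    read_chrom_sizes,
    read_segment_track,
    subtract_blacklist,
    write_segment_track,
)

from conftest import bitmap, make_track, random_track


class TestLayout:
    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})

    def test_exclusion(self, tiny_layout):
        lay = tiny_layout.exclude(["chr2"])
        assert lay.chroms == ["chr1"]
        assert "chr2" not in lay
        assert lay.total_bp == 1000


class TestBedIO:
    def test_single_record(self, tmp_path, tiny_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        t = read_segment_track(p, tiny_layout)
        assert len(t) == 1
        seg = next(iter(t))
        assert (seg.chrom, seg.start, seg.end) == ("chr1", 100, 200)

    def test_empty_file(self, tmp_path, tiny_layout):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_segment_track(p, tiny_layout)) == 0

    @pytest.mark.parametrize("line,match", [
        ("chr1\t900\t1100", "outside chromosome"),
        ("chrX\t10\t20", "unknown chromosome"),
        ("chr1\t200\t100", "start >= end"),
        ("chr1\t100", "columns"),
    ])
    def test_malformed_records(self, tmp_path, tiny_layout, line, match):
        p = tmp_path / "bad.bed"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match=match):
            read_segment_track(p, tiny_layout)

    def test_roundtrip_bit_exact(self, tmp_path, tiny_layout):
        content = "chr1\t5\t10\nchr1\t100\t250\nchr2\t0\t800\n"
        p = tmp_path / "a.bed"
        p.write_text(content)
        t = read_segment_track(p, tiny_layout)
        q = tmp_path / "b.bed"
        write_segment_track(t, q)
        assert q.read_text() == content

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "sizes"
        p.write_text("chr1\t1000\nchr2\t800\n")
        lay = read_chrom_sizes(p)
        assert lay.lengths == {"chr1": 1000, "chr2": 800}


class TestMergeUnion:
    def test_overlapping_pair(self, tiny_layout):
        a = make_track(tiny_layout, [("chr1", 100, 200)])
        b = make_track(tiny_layout, [("chr1", 150, 250)])
        m = merge_union([a, b])
        assert [(s.start, s.end) for s in m] == [(100, 250)]

    def test_disjoint_retained(self, tiny_layout):
        a = make_track(tiny_layout, [("chr1", 0, 10), ("chr1", 50, 60)])
        m = merge_union([a])
        assert [(s.start, s.end) for s in m] == [(0, 10), (50, 60)]

    def test_union_matches_bitmap_oracle(self):
        lay = GenomeLayout({"c1": 5000, "c2": 5000})
        rng = np.random.default_rng(11)
        for _ in range(10):
            tracks = [random_track(lay, rng, n_segments=5) for _ in range(5)]
            merged = merge_union(tracks)
            union_mask = {c: np.zeros(lay.lengths[c], dtype=bool) for c in lay.chroms}
            for t in tracks:
                for c, m in bitmap(t).items():
                    union_mask[c] |= m
            expected = sum(int(m.sum()) for m in union_mask.values())
            assert merged.covered_bp == expected
            # disjointness after merge
            for _, (s, e) in merged.merged_by_chrom().items():
                assert (s[1:] > e[:-1]).all()

    def test_idempotent_and_commutative(self, tiny_layout):
        rng = np.random.default_rng(3)
        a = random_track(tiny_layout, rng, 8)
        b = random_track(tiny_layout, rng, 8)
        assert merge_union([a, a]).covered_bp == a.covered_bp
        assert merge_union([a, b]) == merge_union([b, a])

    def test_mixed_layouts_rejected(self, tiny_layout):
        other = GenomeLayout({"chr1": 999})
        a = make_track(tiny_layout, [("chr1", 0, 10)])
        b = make_track(other, [("chr1", 0, 10)])
        with pytest.raises(ValueError, match="layout"):
            merge_union([a, b])


class TestBlacklist:
    def test_whole_peak_removal(self, tiny_layout):
        peaks = make_track(tiny_layout, [("chr1", 100, 200), ("chr1", 300, 400), ("chr1", 500, 600)])
        bl = make_track(tiny_layout, [("chr1", 120, 180), ("chr1", 399, 450)])
        kept = subtract_blacklist(peaks, bl)
        # inside -> dropped; 1-bp overlap at 399 -> dropped whole; disjoint -> kept intact
        assert [(s.start, s.end) for s in kept] == [(500, 600)]

    def test_one_bp_touch_is_overlap(self, tiny_layout):
        peaks = make_track(tiny_layout, [("chr1", 100, 200)])
        bl = make_track(tiny_layout, [("chr1", 199, 300)])
        assert len(subtract_blacklist(peaks, bl)) == 0
        bl2 = make_track(tiny_layout, [("chr1", 200, 300)])  # book-ended, no shared base
        assert len(subtract_blacklist(peaks, bl2)) == 1


class TestOverlap:
    def test_identical_tracks(self, tiny_layout):
        t = make_track(tiny_layout, [("chr1", 0, 10), ("chr2", 5, 25)])
        assert overlap_bp(t, t) == t.covered_bp == 30

    def test_partial_and_disjoint(self, tiny_layout):
        a = make_track(tiny_layout, [("chr1", 0, 10)])
        b = make_track(tiny_layout, [("chr1", 5, 15)])
        c = make_track(tiny_layout, [("chr1", 500, 600)])
        assert overlap_bp(a, b) == 5
        assert overlap_count(a, b) == 1
        assert overlap_bp(a, c) == 0

    def test_matches_bitmap_oracle(self):
        lay = GenomeLayout({"c1": 3000, "c2": 2000})
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = random_track(lay, rng, 6)
            b = random_track(lay, rng, 6)
            am, bm = bitmap(a), bitmap(b)
            expected_bp = sum(int((am[c] & bm[c]).sum()) for c in lay.chroms)
            assert overlap_bp(a, b) == overlap_bp(b, a) == expected_bp
            expected_count = sum(1 for s in a if bitmap(b)[s.chrom][s.start:s.end].any())
            assert overlap_count(a, b) == expected_count
            assert overlap_bp(a, b) <= min(a.covered_bp, b.covered_bp)


class TestMidpoints:
    @pytest.mark.parametrize("start,end,mid", [(100, 200, 150), (0, 1, 0), (10, 13, 11)])
    def test_floor_midpoint(self, tiny_layout, start, end, mid):
        t = make_track(tiny_layout, [("chr1", start, end)])
        assert midpoints(t).df["pos"].tolist() == [mid]
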