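"""Null-model mechanics: length preservation, exact arrangements, trivial
limits and seed determinism."""

import numpy as np
import pandas as pd
import pytest

from vdrcohort.annotation import Gene, GeneModel
from vdrcohort.enrichment import (
    CaseControlTrack,
    IntensityTrack,
    build_gene_proximity_intensity,
    mc_case_control,
    mc_point_segment,
    mc_segment_segment,
    randomize_preserving_lengths,
)
from vdrcohort.genome import GenomeLayout, PointTrack, SegmentTrack, midpoints

from conftest import make_track, random_track


def lengths_and_gaps(track, chrom):
    # raw arrays: a zero gap may sit between segments after randomization
    s, e = track.by_chrom()[chrom]
    L = track.layout.lengths[chrom]
    gaps = np.concatenate(([s[0]], s[1:] - e[:-1], [L - e[-1]]))
    return sorted(e - s), sorted(gaps)


class TestRandomization:
    def test_preserves_length_and_gap_multisets(self):
        lay = GenomeLayout({"c1": 5000, "c2": 3000})
        rng = np.random.default_rng(2)
        track = random_track(lay, rng, n_segments=12, max_len=100).merged()
        for _ in range(100):
            r = randomize_preserving_lengths(track, rng=rng)
            for chrom in r.merged_by_chrom():
                assert lengths_and_gaps(r, chrom) == lengths_and_gaps(track, chrom)

    def test_two_arrangement_chromosome(self):
        # one segment of length 4 on a 10 bp chromosome with gaps {2, 4}:
        # the only possible starts are 2 and 4, each with probability 1/2
        lay = GenomeLayout({"c": 10})
        track = make_track(lay, [("c", 2, 6)])
        rng = np.random.default_rng(0)
        starts = [randomize_preserving_lengths(track, rng=rng).df["start"].iloc[0]
                  for _ in range(4000)]
        counts = pd.Series(starts).value_counts()
        assert set(counts.index) == {2, 4}
        # binomial(4000, 1/2): 3 sigma ~ 95
        assert abs(counts[2] - 2000) < 120

    def test_empty_and_saturated_tracks(self):
        lay = GenomeLayout({"c": 100})
        empty = make_track(lay, [])
        assert len(randomize_preserving_lengths(empty, rng=0)) == 0
        full = make_track(lay, [("c", 0, 100)])
        r = randomize_preserving_lengths(full, rng=0)
        assert [(s.start, s.end) for s in r] == [(0, 100)]


class TestSegmentSegment:
    def test_reference_covering_genome(self):
        lay = GenomeLayout({"c": 1000})
        q = make_track(lay, [("c", 100, 200), ("c", 300, 450)])
        ref = make_track(lay, [("c", 0, 1000)])
        res = mc_segment_segment(q, ref, n=99, rng=0)
        assert res.observed == res.expected == q.covered_bp
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_self_overlap_minimal_p(self):
        # query == reference, half the genome split into distinct blocks:
        # only exact reconstruction reaches the observed overlap
        lay = GenomeLayout({"c": 10_000})
        blocks = [("c", 0, 400), ("c", 900, 2100), ("c", 2400, 3100),
                  ("c", 3900, 4400), ("c", 6000, 7600), ("c", 8100, 8200)]
        t = make_track(lay, blocks)
        res = mc_segment_segment(t, t, n=999, rng=1)
        assert res.fold is not None and res.fold > 1
        assert res.p_value == pytest.approx(1 / 1000)

    def test_seed_determinism(self):
        lay = GenomeLayout({"c": 5000})
        rng = np.random.default_rng(4)
        q = random_track(lay, rng, 8).merged()
        ref = random_track(lay, rng, 8).merged()
        r1 = mc_segment_segment(q, ref, n=200, seed=42)
        r2 = mc_segment_segment(q, ref, n=200, seed=42)
        assert (r1.expected, r1.p_value) == (r2.expected, r2.p_value)

    def test_zero_expected_reports_missing_fold(self):
        # reference on a chromosome the query never visits
        lay = GenomeLayout({"c1": 1000, "c2": 1000})
        q = make_track(lay, [("c1", 0, 100)])
        ref = make_track(lay, [("c2", 0, 100)])
        res = mc_segment_segment(q, ref, n=49, rng=0)
        assert res.fold is None
        assert res.observed == 0


class TestIntensity:
    def test_points_inside_genes_weight_on_class_zero(self):
        lay = GenomeLayout({"c": 100_000})
        gene = Gene("g", "c", "+", 40_000, 60_000, exons=((40_000, 60_000),))
        model = GeneModel(lay, [gene])
        pts = PointTrack(lay, [("c", 45_000), ("c", 55_000), ("c", 50_000)])
        it = build_gene_proximity_intensity(pts, model, bin_size=10_000)
        w = it.weights["c"]
        assert w.sum() == pytest.approx(1.0)
        # only bins whose centers fall inside the gene carry weight
        assert w[4] > 0 and w[5] > 0
        assert w[[0, 1, 2, 8, 9]].sum() == pytest.approx(0.0)

    def test_uniform_points_resample_uniformly(self):
        lay = GenomeLayout({"c": 100_000})
        gene = Gene("g", "c", "+", 0, 1000, exons=((0, 1000),))
        model = GeneModel(lay, [gene])
        rng = np.random.default_rng(3)
        pts = PointTrack(lay, [("c", int(p)) for p in rng.integers(0, 100_000, 400)])
        it = build_gene_proximity_intensity(pts, model, bin_size=5000)
        sampled = it.sample_points(3000, rng)["c"]
        # coarse halves comparison: roughly as many resampled points per half
        # as observed points per half
        obs_left = (pts.df["pos"] < 50_000).mean()
        samp_left = (sampled < 50_000).mean()
        assert abs(obs_left - samp_left) < 0.08

    def test_single_bin_genome(self):
        lay = GenomeLayout({"c": 500})
        gene = Gene("g", "c", "+", 0, 500, exons=((0, 500),))
        pts = PointTrack(lay, [("c", 10)])
        it = build_gene_proximity_intensity(pts, GeneModel(lay, [gene]), bin_size=1000)
        assert it.weights["c"].tolist() == [1.0]

    def test_no_genes_errors(self):
        lay = GenomeLayout({"c": 500})
        pts = PointTrack(lay, [("c", 10)])
        with pytest.raises(ValueError, match="empty"):
            build_gene_proximity_intensity(pts, GeneModel(lay, []), bin_size=100)


class TestPointSegment:
    def test_segments_covering_genome(self):
        lay = GenomeLayout({"c": 10_000})
        pts = PointTrack(lay, [("c", p) for p in (5, 500, 7000)])
        segs = make_track(lay, [("c", 0, 10_000)])
        it = IntensityTrack(lay, 1000, {"c": np.full(10, 0.1)})
        res = mc_point_segment(pts, segs, it, n=99, rng=0)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_uniform_intensity_expected_half(self):
        lay = GenomeLayout({"c": 100_000})
        rng = np.random.default_rng(1)
        pts = PointTrack(lay, [("c", int(p)) for p in rng.integers(0, 100_000, 100)])
        segs = make_track(lay, [("c", 0, 50_000)])
        it = IntensityTrack(lay, 1000, {"c": np.full(100, 0.01)})
        res = mc_point_segment(pts, segs, it, n=400, rng=2)
        # binomial(100, 0.5): null mean within ~3 sigma/sqrt(400) of 50
        assert abs(res.expected - 50.0) < 1.5

    def test_excluding_chromosome_with_all_segments(self):
        lay = GenomeLayout({"c1": 10_000, "c2": 10_000})
        pts = PointTrack(lay, [("c1", 100), ("c2", 5000)])
        segs = make_track(lay, [("c2", 0, 10_000)])
        it = IntensityTrack(lay, 1000, {"c1": np.full(10, 0.05), "c2": np.full(10, 0.05)})
        res = mc_point_segment(pts, segs, it, n=49, rng=0, exclude_chroms=["c2"])
        assert res.observed == 0


class TestCaseControl:
    def _track(self, lay, blocks):
        return make_track(lay, blocks)

    def test_identical_rates_give_null_statistic(self):
        lay = GenomeLayout({"c": 10_000})
        t = self._track(lay, [("c", 0, 100), ("c", 200, 300), ("c", 400, 500), ("c", 600, 700)])
        ref = self._track(lay, [("c", 0, 10_000)])  # everything overlaps fully
        cc = CaseControlTrack(t, np.array([True, True, False, False]))
        res = mc_case_control(cc, ref, n=199, rng=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_matches_enumeration(self):
        # 4 case segments inside the reference, 4 control far away:
        # |T| is maximal only when the labels are exactly right or exactly
        # flipped -> exact two-sided p = 2/C(8,4) = 2/70
        lay = GenomeLayout({"c": 100_000})
        blocks = [("c", i * 1000, i * 1000 + 100) for i in range(8)]
        t = self._track(lay, blocks)
        ref = self._track(lay, [("c", 0, 3101)])  # covers the 4 case segments
        labels = np.array([True] * 4 + [False] * 4)
        cc = CaseControlTrack(t, labels)
        res = mc_case_control(cc, ref, n=9999, rng=3)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / 70, rel=0.25)

    def test_both_labels_required(self):
        lay = GenomeLayout({"c": 1000})
        t = self._track(lay, [("c", 0, 10), ("c", 20, 30)])
        with pytest.raises(ValueError, match="label"):
            CaseControlTrack(t, np.array([True, True]))
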