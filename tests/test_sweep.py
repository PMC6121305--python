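import numpy as np
import pandas as pd
import pytest

from crosspopgen.association import QTLRegion
from crosspopgen.simdata import CrossDesign, simulate_divergent_pair, uniform_map
from crosspopgen.sweep import (
    SegmentScores,
    SelectionSignature,
    SweepScoreTrack,
    XPCLRParams,
    call_signatures,
    qtl_sweep_overlap,
    segment_scores,
    xpclr_score,
)

from .conftest import make_cross


def track_from(chrom, pos, score, n_snps=None, params=None):
    n_snps = n_snps if n_snps is not None else [1] * len(pos)
    return SweepScoreTrack(
        scores=pd.DataFrame(
            {"chrom": chrom, "pos_bp": pos, "score": score, "n_snps": n_snps}
        ),
        params=params or XPCLRParams(),
    )


def segments_from(xmax_by_chrom, segment_bp=10_000):
    rows = []
    vals = []
    for chrom, xs in xmax_by_chrom.items():
        for s, x in enumerate(xs):
            defined = x is not None
            rows.append(
                (chrom, s, s * segment_bp + 1, (s + 1) * segment_bp,
                 np.nan if x is None else float(x), defined)
            )
            if defined:
                vals.append(float(x))
    df = pd.DataFrame(
        rows, columns=["chrom", "seg_index", "start_bp", "end_bp", "x_max", "defined"]
    )
    return SegmentScores(segments=df, segment_bp=segment_bp,
                         x80=float(np.percentile(vals, 80)))


class TestXpclrScore:
    def test_identical_populations_score_near_zero(self, tiny_map):
        a = make_cross(tiny_map, "RIL_F6", 80, seed=1, label="A")
        b = a.take_lines(np.arange(80))
        b.line_ids = np.array([f"B{i}" for i in range(80)], dtype=object)
        tr = xpclr_score(a, b, XPCLRParams(window_morgan=0.05, grid_size_bp=100_000))
        assert tr.scores["score"].max() < 0.5

    def test_scores_finite_nonnegative_grid_increasing(self, tiny_map):
        a = make_cross(tiny_map, "RIL_F6", 60, seed=2, label="A")
        b = make_cross(tiny_map, "RIL_F6", 60, seed=3, label="B")
        tr = xpclr_score(a, b, XPCLRParams(window_morgan=0.05, grid_size_bp=200_000))
        assert (tr.scores["score"] >= 0).all()
        assert np.isfinite(tr.scores["score"]).all()
        for _, grp in tr.scores.groupby("chrom"):
            assert (np.diff(grp["pos_bp"]) > 0).all()

    def test_allele_label_swap_invariance(self, tiny_map):
        from .test_genotypes import make_matrix

        a = make_cross(tiny_map, "RIL_F6", 60, seed=4, label="A")
        b = make_cross(tiny_map, "RIL_F6", 60, seed=5, label="B")
        params = XPCLRParams(window_morgan=0.05, grid_size_bp=500_000)
        t1 = xpclr_score(a, b, params)
        a_sw = make_matrix((2 - a.calls).astype(np.int8))
        a_sw.markers = a.markers.copy()
        b_sw = make_matrix((2 - b.calls).astype(np.int8))
        b_sw.markers = b.markers.copy()
        b_sw.line_ids = np.array([f"B{i}" for i in range(60)], dtype=object)
        t2 = xpclr_score(a_sw, b_sw, params)
        np.testing.assert_allclose(t1.scores["score"], t2.scores["score"], atol=1e-8)

    def test_permuted_labels_drop_selected_score(self):
        """Permuting lines between populations removes the sweep contrast."""
        gmap = uniform_map(2, 20_000_000, 300, cm_per_mb=2.0)
        m = gmap.n_markers
        pa, pb = np.zeros(m, np.int8), np.ones(m, np.int8)
        locus = gmap.markers["marker_id"].iloc[150]
        a, b = simulate_divergent_pair(
            gmap,
            CrossDesign("RIL_F6", 90, pa, pb, seed=31),
            CrossDesign("RIL_F6", 90, pa, pb, seed=32),
            locus,
            0.8,
        )
        params = XPCLRParams(grid_size_bp=10_000)
        tr = xpclr_score(a, b, params)
        lbp = int(gmap.markers["pos_bp"].iloc[150])
        sel = tr.scores[(tr.scores["chrom"] == "chr1")
                        & (abs(tr.scores["pos_bp"] - lbp) < 100_000)]["score"].max()
        rng = np.random.default_rng(33)
        allc = np.vstack([a.calls, b.calls])
        perm = rng.permutation(180)
        a2 = a.take_lines(np.arange(90))
        a2.calls = allc[perm[:90]]
        b2 = b.take_lines(np.arange(90))
        b2.calls = allc[perm[90:]]
        tr2 = xpclr_score(a2, b2, params)
        assert np.percentile(tr2.scores["score"], 95) < sel

    def test_too_few_shared_snps_raises(self, tiny_map):
        a = make_cross(tiny_map, "RIL_F6", 30, seed=6, label="A")
        b = a.take_markers(np.array([0]))
        a1 = a.take_markers(np.array([0]))
        with pytest.raises(ValueError):
            xpclr_score(a1, b, XPCLRParams())


class TestSegmentScores:
    def test_constant_score_everywhere(self):
        pos = np.arange(1000, 50_001, 1000)
        tr = track_from("chr1", pos, np.full(pos.size, 3.0))
        segs = segment_scores(tr)
        defined = segs.segments[segs.segments["defined"]]
        assert (defined["x_max"] == 3.0).all()
        assert segs.x80 == 3.0

    def test_max_rule_assigns_peak_to_its_segment(self):
        pos = np.array([5_000, 15_000, 25_000, 35_000])
        tr = track_from("chr1", pos, [1.0, 1.0, 10.0, 1.0])
        segs = segment_scores(tr)
        seg = segs.segments
        assert seg.loc[seg["seg_index"] == 2, "x_max"].iloc[0] == 10.0

    def test_matches_brute_force_maxima(self):
        rng = np.random.default_rng(7)
        pos = np.arange(500, 100_001, 500)
        score = rng.exponential(size=pos.size)
        n_snps = rng.integers(0, 3, size=pos.size)
        tr = track_from("chr1", pos, score, n_snps=n_snps)
        segs = segment_scores(tr, segment_bp=10_000)
        for row in segs.segments.itertuples(index=False):
            in_seg = (pos - 1) // 10_000 == row.seg_index
            valid = in_seg & (n_snps >= 1)
            if valid.any():
                assert row.defined
                assert row.x_max == pytest.approx(score[valid].max())
            else:
                assert not row.defined

    def test_undefined_segments_excluded_from_percentile(self):
        pos = np.array([5_000, 15_000, 25_000])
        tr = track_from("chr1", pos, [50.0, 1.0, 1.0], n_snps=[0, 1, 1])
        segs = segment_scores(tr)
        assert segs.x80 == pytest.approx(1.0)  # the 50 is in an undefined segment


class TestCallSignatures:
    def test_uniform_scores_yield_nothing(self):
        segs = segments_from({"chr1": [2.0] * 30})
        assert call_signatures(segs) == []

    def test_two_runs_with_single_gap_merge(self):
        xs = [0.0] * 5 + [5.0, 5.0] + [0.0] + [5.0, 5.0] + [0.0] * 20
        segs = segments_from({"chr1": xs})
        sigs = call_signatures(segs)
        assert len(sigs) == 1
        assert sigs[0].start_bp == 5 * 10_000 + 1
        assert sigs[0].end_bp == 10 * 10_000

    def test_hand_traced_thirty_segments(self):
        """Two separated peaks on a crafted score vector, traced by hand.

        Segments (index: score): 3,4 high (run A); 6,7 high (run B, one low
        segment between A and B -> merge into [3..7]); 20,21,22 high (run C,
        far away).  x80 splits at the 80th percentile of all 30 scores.
        Merged sweep scores: A+B -> 9, C -> 7.  The 90th percentile of
        {9, 7} is 8.8, so only the first signature survives.
        """
        xs = [1.0] * 30
        xs[3], xs[4] = 8.0, 9.0
        xs[6], xs[7] = 8.5, 8.0
        xs[20], xs[21], xs[22] = 7.0, 6.5, 6.0
        segs = segments_from({"chr1": xs})
        assert segs.x80 == pytest.approx(np.percentile(xs, 80))
        sigs = call_signatures(segs)
        assert len(sigs) == 1
        assert sigs[0].start_bp == 3 * 10_000 + 1
        assert sigs[0].end_bp == 8 * 10_000
        assert sigs[0].score == 9.0

    def test_single_high_segment_is_not_a_sweep(self):
        xs = [0.0] * 10 + [9.0] + [0.0] * 19
        segs = segments_from({"chr1": xs})
        assert call_signatures(segs) == []

    def test_output_disjoint_sorted_and_above_cut(self):
        rng = np.random.default_rng(8)
        xs = list(rng.exponential(size=60))
        segs = segments_from({"chr1": xs[:30], "chr2": xs[30:]})
        sigs = call_signatures(segs)
        for a, b in zip(sigs[:-1], sigs[1:]):
            if a.chrom == b.chrom:
                assert a.end_bp < b.start_bp

    def test_planted_sweep_recovered(self):
        """A selected locus (intensity 0.8) is covered by a called signature
        in >= 80% of 20 seeds."""
        hits = 0
        for seed in range(20):
            gmap = uniform_map(2, 20_000_000, 300, cm_per_mb=2.0)
            m = gmap.n_markers
            pa, pb = np.zeros(m, np.int8), np.ones(m, np.int8)
            locus = gmap.markers["marker_id"].iloc[150]
            lbp = int(gmap.markers["pos_bp"].iloc[150])
            a, b = simulate_divergent_pair(
                gmap,
                CrossDesign("RIL_F6", 90, pa, pb, seed=1000 + seed),
                CrossDesign("RIL_F6", 90, pa, pb, seed=2000 + seed),
                locus,
                0.8,
            )
            tr = xpclr_score(a, b, XPCLRParams(grid_size_bp=5000))
            sigs = call_signatures(segment_scores(tr))
            hits += any(
                s.chrom == "chr1" and s.start_bp <= lbp <= s.end_bp for s in sigs
            )
        assert hits >= 16


class TestOverlap:
    def qtl(self, start, end, chrom="chr1"):
        return QTLRegion(
            qtl_id="q1", trait="t", chrom=chrom, start_bp=start, end_bp=end,
            peak_marker="m", peak_p=1e-9, member_markers=["m"],
        )

    def sig(self, start, end, chrom="chr1"):
        return SelectionSignature(chrom=chrom, start_bp=start, end_bp=end,
                                  score=10.0, n_segments=2)

    def test_gap_within_flank_associates(self):
        out = qtl_sweep_overlap([self.sig(1_050_000, 1_150_000)],
                                [self.qtl(1_000_000, 1_000_000)], flank_kb=100)
        assert len(out) == 1

    def test_gap_beyond_flank_does_not(self):
        out = qtl_sweep_overlap([self.sig(1_210_000, 1_300_000)],
                                [self.qtl(1_000_000, 1_100_000)], flank_kb=100)
        assert len(out) == 0

    def test_exact_boundary_touch_counts(self):
        out = qtl_sweep_overlap([self.sig(1_100_000, 1_200_000)],
                                [self.qtl(900_000, 1_000_000)], flank_kb=100)
        assert len(out) == 1  # closed intervals: extended edge touches start

    def test_different_chromosomes_never_associate(self):
        out = qtl_sweep_overlap([self.sig(1_000_000, 1_100_000, chrom="chr2")],
                                [self.qtl(1_000_000, 1_100_000)], flank_kb=100)
        assert len(out) == 0
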