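import numpy as np
import pandas as pd
import pytest

from crosspopgen.popgen import (
    LDDecayModel,
    blocks_to_bed,
    fit_ld_decay,
    fst,
    haplotype_blocks,
    hill_weir_expected_r2,
    nucleotide_diversity,
    pairwise_r2,
    prune_ld,
)
from crosspopgen.simdata import CrossDesign, GeneticMap, simulate_biparental_cross, uniform_map

from ._oracles import direct_r2, mean_pairwise_differences
from .conftest import make_cross
from .test_genotypes import make_matrix


class TestPairwiseR2:
    def test_duplicated_marker_r2_one(self):
        col = np.array([0, 0, 2, 2, 0, 2], dtype=np.int8)
        g = make_matrix(np.column_stack([col, col]))
        pairs = pairwise_r2(g)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_pair_r2_zero(self):
        g = make_matrix(np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=np.int8))
        pairs = pairwise_r2(g)
        assert pairs["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2], size=(20, 5)).astype(np.int8)
        g = make_matrix(calls)
        pairs = pairwise_r2(g)
        x = g.dosages()
        ids = list(g.markers["marker_id"])
        for row in pairs.itertuples(index=False):
            i, j = ids.index(row.marker_i), ids.index(row.marker_j)
            assert row.r2 == pytest.approx(direct_r2(x[:, i], x[:, j]), abs=1e-10)

    def test_window_limit_respected(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([0, 2], size=(30, 10)).astype(np.int8)
        g = make_matrix(calls, step=1_000_000)
        pairs = pairwise_r2(g, max_window_kb=2500)
        assert (pairs["dist_bp"] <= 2_500_000).all()

    def test_monomorphic_only_raises(self):
        g = make_matrix(np.zeros((10, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            pairwise_r2(g)


class TestPrune:
    def test_identical_adjacent_markers_one_removed(self):
        col = np.array([0, 2, 0, 2, 2, 0], dtype=np.int8)
        g = make_matrix(np.column_stack([col, col, 2 - col]))
        out = prune_ld(g, r2_max=0.9)
        assert out.n_markers == 1  # all three mutually |r| = 1

    def test_low_ld_is_identity(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 2], size=(200, 8)).astype(np.int8)
        g = make_matrix(calls, step=500_000)
        out = prune_ld(g, r2_max=0.9)
        assert out.n_markers == g.n_markers  # independent markers, r2 ~ 0

    def test_post_audit_no_surviving_high_ld_pair(self, study_map):
        """Exhaustive audit: pruned output has no in-window pair above r2_max."""
        g = make_cross(study_map, "RIL_F6", 80, seed=17)
        chr1 = np.flatnonzero(g.markers["chrom"] == "chr1")
        g = g.take_markers(chr1[:200] if chr1.size >= 200 else chr1)
        out = prune_ld(g, window_kb=2000, r2_max=0.9)
        pairs = pairwise_r2(out, max_window_kb=2000)
        assert (pairs["r2"] <= 0.9 + 1e-12).all()
        # pruning is a subset and re-pruning is the identity
        assert set(out.markers["marker_id"]).issubset(set(g.markers["marker_id"]))
        again = prune_ld(out, window_kb=2000, r2_max=0.9)
        assert list(again.markers["marker_id"]) == list(out.markers["marker_id"])

    def test_r2_max_validation(self):
        g = make_matrix(np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            prune_ld(g, r2_max=1.5)


class TestLDDecay:
    def test_noise_free_recovery_within_tenth_percent(self):
        rng = np.random.default_rng(0)
        d = rng.integers(100, 2_000_000, size=400)
        c_true = 1e-5
        pairs = pd.DataFrame({"dist_bp": d, "r2": hill_weir_expected_r2(c_true * d, 520)})
        fit = fit_ld_decay(pairs, 520)
        assert abs(fit.c - c_true) / c_true < 1e-3

    def test_zero_distance_limit_is_ten_over_22(self):
        assert hill_weir_expected_r2(np.array(0.0), 10**9) == pytest.approx(10 / 22, abs=1e-6)

    def test_doubling_c_halves_half_decay(self):
        rng = np.random.default_rng(1)
        d = rng.integers(100, 2_000_000, size=400)
        f1 = fit_ld_decay(
            pd.DataFrame({"dist_bp": d, "r2": hill_weir_expected_r2(1e-5 * d, 520)}), 520
        )
        f2 = fit_ld_decay(
            pd.DataFrame({"dist_bp": d, "r2": hill_weir_expected_r2(2e-5 * d, 520)}), 520
        )
        assert f1.half_decay_bp / f2.half_decay_bp == pytest.approx(2.0, rel=1e-4)

    def test_curve_positive_and_strictly_decreasing(self):
        d = np.linspace(1, 5_000_000, 200)
        for c in (1e-6, 1e-5, 1e-4):
            for n in (2, 10, 520):
                y = hill_weir_expected_r2(c * d, n)
                assert (y > 0).all()
                assert (np.diff(y) < 0).all()

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            LDDecayModel(pd.DataFrame({"dist_bp": [1] * 12, "r2": [0.5] * 12}), 100)
        with pytest.raises(ValueError):
            LDDecayModel(pd.DataFrame({"dist_bp": [1, 2], "r2": [0.5, 0.4]}), 100)

    def test_results_summary_has_model_fields(self):
        rng = np.random.default_rng(2)
        d = rng.integers(100, 2_000_000, size=100)
        fit = fit_ld_decay(
            pd.DataFrame({"dist_bp": d, "r2": hill_weir_expected_r2(1e-5 * d, 200)}), 200
        )
        s = fit.summary()
        assert {"c", "half_decay_kb", "r2_at_zero"} <= set(s.columns)


class TestDiversity:
    def test_identical_lines_zero_pi(self):
        g = make_matrix(np.tile(np.array([0, 2, 2], dtype=np.int8), (5, 1)))
        d = nucleotide_diversity(g)
        assert d.pi_per_site == 0.0
        assert d.pi_total == 0.0

    def test_single_site_closed_form(self):
        # p = 0.5 with 4 allele copies: pi = 2 * 0.25 * 4/3
        g = make_matrix(np.array([[0], [2]], dtype=np.int8))
        d = nucleotide_diversity(g)
        assert d.pi_per_site == pytest.approx(2 * 0.25 * 4 / 3)

    def test_matches_pairwise_difference_oracle(self):
        rng = np.random.default_rng(6)
        calls = rng.choice([0, 1, 2], size=(6, 10)).astype(np.int8)
        g = make_matrix(calls)
        d = nucleotide_diversity(g)
        assert d.pi_total + (d.pi_per_site == d.pi_per_site) >= 0  # finite
        assert d.pi_total == pytest.approx(
            mean_pairwise_differences(calls), rel=1e-9
        )

    def test_line_order_invariance(self):
        rng = np.random.default_rng(7)
        calls = rng.choice([0, 1, 2], size=(8, 6)).astype(np.int8)
        g = make_matrix(calls)
        g2 = g.take_lines(rng.permutation(8))
        assert nucleotide_diversity(g).pi_total == pytest.approx(
            nucleotide_diversity(g2).pi_total
        )


class TestFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([0, 2], size=(400, 30)).astype(np.int8)
        a = make_matrix(calls[:200])
        b = make_matrix(calls[200:])
        b.line_ids = np.array([f"B{i}" for i in range(200)], dtype=object)
        assert abs(fst(a, b)) < 0.02

    def test_fixed_differences_give_one(self):
        a = make_matrix(np.zeros((10, 5), dtype=np.int8))
        b = make_matrix(np.full((10, 5), 2, dtype=np.int8))
        assert fst(a, b) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        """p1 = 0.2, p2 = 0.8 at every site; compare to the estimator formula."""
        n1 = n2 = 50
        a_calls = np.zeros((n1, 4), dtype=np.int8)
        a_calls[:10] = 2  # p1 = 0.2
        b_calls = np.zeros((n2, 4), dtype=np.int8)
        b_calls[:40] = 2  # p2 = 0.8
        a, b = make_matrix(a_calls), make_matrix(b_calls)
        b.line_ids = np.array([f"B{i}" for i in range(n2)], dtype=object)
        p1, p2 = 0.2, 0.8
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert fst(a, b) == pytest.approx(num / den, rel=1e-9)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(9)
        a = make_matrix(rng.choice([0, 2], size=(30, 10)).astype(np.int8))
        b = make_matrix(rng.choice([0, 2], size=(30, 10), p=[0.8, 0.2]).astype(np.int8))
        b.line_ids = np.array([f"B{i}" for i in range(30)], dtype=object)
        a_sw = make_matrix((2 - a.calls).astype(np.int8))
        b_sw = make_matrix((2 - b.calls).astype(np.int8))
        b_sw.line_ids = b.line_ids
        assert fst(a, b) == pytest.approx(fst(a_sw, b_sw), rel=1e-9)

    def test_no_shared_polymorphic_site_raises(self):
        a = make_matrix(np.zeros((5, 3), dtype=np.int8))
        b = make_matrix(np.zeros((5, 3), dtype=np.int8))
        b.line_ids = np.array([f"B{i}" for i in range(5)], dtype=object)
        with pytest.raises(ValueError):
            fst(a, b)


class TestHaplotypeBlocks:
    def test_identical_marker_run_single_block(self):
        rng = np.random.default_rng(10)
        col = rng.choice([0, 2], size=40).astype(np.int8)
        calls = np.tile(col[:, None], (1, 6))
        g = make_matrix(calls, step=10_000)
        blocks = haplotype_blocks(g)
        assert len(blocks) == 1
        assert len(blocks[0].marker_ids) == 6

    def test_linkage_equilibrium_zero_blocks(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([0, 2], size=(80, 10)).astype(np.int8)
        g = make_matrix(calls, step=10_000)
        assert haplotype_blocks(g) == []

    def test_planted_low_recombination_region_recovered(self):
        """A 500-kb tight-LD region flanked by free recombination is found
        with boundaries within +/- 2 markers, across 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 100
            outer_left = rng.choice([0, 2], size=(n, 5)).astype(np.int8)
            core_hap = rng.choice([0, 2], size=n).astype(np.int8)
            # 10 markers at 50-kb spacing sharing one haplotype (rare breakdowns)
            core = np.tile(core_hap[:, None], (1, 10))
            flip = rng.random((n, 10)) < 0.02
            core[flip] = 2 - core[flip]
            outer_right = rng.choice([0, 2], size=(n, 5)).astype(np.int8)
            calls = np.hstack([outer_left, core, outer_right]).astype(np.int8)
            g = make_matrix(calls, step=50_000)
            blocks = haplotype_blocks(g, max_block_kb=2000)
            for b in blocks:
                member_idx = [list(g.markers["marker_id"]).index(mid) for mid in b.marker_ids]
                if abs(member_idx[0] - 5) <= 2 and abs(member_idx[-1] - 14) <= 2:
                    hits += 1
                    break
        assert hits >= 8

    def test_bed_conversion_half_open(self):
        rng = np.random.default_rng(12)
        col = rng.choice([0, 2], size=30).astype(np.int8)
        g = make_matrix(np.tile(col[:, None], (1, 4)), start=1001, step=1000)
        bed = blocks_to_bed(haplotype_blocks(g))
        assert bed["start"].iloc[0] == 1000  # 1-based 1001 -> 0-based 1000
        assert bed["end"].iloc[0] == 4001
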