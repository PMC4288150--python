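import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mutrscan import (CallerConfig, GeneFeature, Segment, assign_to_gene,
                      bh_adjust, call_mutrs, correlate, filter_unannotated,
                      sporulation_specific)
from mutrscan.io import AnnotationError

from .conftest import make_expr

CFG = CallerConfig()


class TestFilterUnannotated:
    orf = GeneFeature("g1", "chr1", "+", 1000, 2000)
    trna = GeneFeature("t1", "chr1", "+", 3000, 3100, feature_class="tRNA")

    def test_segment_inside_orf_same_strand_removed(self):
        seg = Segment("s", "chr1", "+", 1100, 1200)
        assert filter_unannotated([seg], [self.orf]) == []

    def test_opposite_strand_overlap_retained(self):
        seg = Segment("s", "chr1", "-", 3000, 3100)
        assert filter_unannotated([seg], [self.trna]) == [seg]

    def test_single_base_overlap_excludes(self):
        seg = Segment("s", "chr1", "+", 999, 1001)
        assert filter_unannotated([seg], [self.orf]) == []

    def test_no_annotation_retains_all(self):
        segs = [Segment("s", "chr1", "+", 0, 10)]
        assert filter_unannotated(segs, []) == segs


class TestSporulationSpecific:
    def test_two_spii_timepoints_suffice(self):
        expr = make_expr({"s": {"SPII_04h": 8.0, "SPII_05h": 8.0}})
        assert sporulation_specific(expr, "s", CFG)

    def test_mitotic_expression_disqualifies(self):
        expr = make_expr({"s": {"SPII_04h": 8.0, "SPII_05h": 8.0, "YPD": 8.0}})
        assert not sporulation_specific(expr, "s", CFG)

    def test_starvation_expression_disqualifies(self):
        expr = make_expr({"s": {"SPII_04h": 8.0, "SPII_05h": 8.0, "aa_SPII_08h": 8.0}})
        assert not sporulation_specific(expr, "s", CFG)

    def test_exactly_tau_everywhere_is_not_above_background(self):
        expr = make_expr({"s": CFG.tau})
        assert not sporulation_specific(expr, "s", CFG)

    def test_single_spii_timepoint_insufficient(self):
        expr = make_expr({"s": {"SPII_04h": 8.0}})
        assert not sporulation_specific(expr, "s", CFG)


class TestAssignToGene:
    def test_five_prime_gap_convention(self):
        gene = GeneFeature("g1", "chr1", "+", 1000, 2000)
        seg = Segment("s", "chr1", "+", 920, 995)
        assert assign_to_gene(seg, [gene], CFG) == ("g1", "5p", 5)

    def test_beyond_max_gap_unassigned(self):
        gene = GeneFeature("g1", "chr1", "+", 1000, 2000)
        seg = Segment("s", "chr1", "+", 700, 850)  # 150 bp upstream
        assert assign_to_gene(seg, [gene], CFG) is None

    def test_smallest_gap_wins(self):
        near = GeneFeature("g_near", "chr1", "+", 1010, 2000)
        far = GeneFeature("g_far", "chr1", "+", 1040, 2100)
        seg = Segment("s", "chr1", "+", 900, 1000)
        assert assign_to_gene(seg, [near, far], CFG) == ("g_near", "5p", 10)

    def test_equal_gap_ties_break_lexicographically(self):
        a = GeneFeature("gA", "chr1", "+", 1010, 2000)
        b = GeneFeature("gB", "chr1", "+", 1010, 2050)
        seg = Segment("s", "chr1", "+", 900, 1000)
        assert assign_to_gene(seg, [b, a], CFG)[0] == "gA"

    def test_minus_strand_three_prime(self):
        # terminator of a - strand gene is its left boundary
        gene = GeneFeature("g1", "chr1", "-", 1000, 2000)
        seg = Segment("s", "chr1", "-", 800, 980)
        assert assign_to_gene(seg, [gene], CFG) == ("g1", "3p", 20)

    def test_abutting_anchor_counts_as_gap_zero(self):
        gene = GeneFeature("g1", "chr1", "+", 1000, 2000)
        seg = Segment("s", "chr1", "+", 900, 1000)
        assert assign_to_gene(seg, [gene], CFG) == ("g1", "5p", 0)

    def test_opposite_strand_never_assigned(self):
        gene = GeneFeature("g1", "chr1", "-", 1000, 2000)
        seg = Segment("s", "chr1", "+", 920, 995)
        assert assign_to_gene(seg, [gene], CFG) is None


class TestCorrelate:
    def test_identical_rows_fully_correlated(self):
        x = np.arange(14, dtype=float)
        res = correlate(x, x)
        assert res.cc == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_rows_give_p_one(self):
        x = np.tile([1.0, -1.0], 7)
        y = np.concatenate([np.tile([1.0, 1.0, -1.0, -1.0], 3), [0.0, 0.0]])
        assert float(x @ y) == 0.0 and x.mean() == y.mean() == 0.0
        res = correlate(x, y)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_p_matches_closed_form_t_tail(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=14), rng.normal(size=14)
        res = correlate(x, y)
        cc = np.corrcoef(x, y)[0, 1]
        t = cc * math.sqrt(12 / (1 - cc**2))
        expected = 2 * (1 - sps.t.cdf(abs(t), 12))
        assert res.df == 12 and res.n == 14
        assert res.p_raw == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_flagged_null(self):
        res = correlate(np.zeros(14), np.arange(14, dtype=float))
        assert res.cc == 0.0 and res.p_raw == 1.0
        assert "degenerate_variance" in res.flags

    def test_wrong_design_size_fails(self):
        with pytest.raises(AnnotationError, match="14"):
            correlate(np.zeros(13), np.zeros(13))


def brute_force_bh(p):
    """Step-up definition: adj_i = min over j with p_(j) >= p_(i) of m*p_(j)/j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


class TestBHAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_matches_brute_force_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 5), [0.3] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=6))
    def test_matches_brute_force_for_short_vectors(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestCallMutrs:
    def test_empty_segments_give_empty_calls(self, genome, expr):
        calls, report = call_mutrs([], genome.genes, expr)
        assert calls == [] and len(report) == 0

    def test_alpha_one_selects_nothing(self, genome, expr):
        calls, report = call_mutrs(genome.segments, genome.genes, expr,
                                   CallerConfig(alpha=1.0))
        assert calls == []
        assert len(report) > 0  # candidates were evaluated, none selected

    def test_recovers_planted_and_rejects_decoys(self, genome, expr):
        calls, _ = call_mutrs(genome.segments, genome.genes, expr)
        called = {c.segment_id for c in calls}
        planted = set(genome.truth.loc[genome.truth["kind"] == "mutr", "segment_id"])
        assert called == planted
        for call in calls:
            row = genome.truth.set_index("segment_id").loc[call.segment_id]
            assert call.gene_id == row["gene_id"] and call.side == row["side"]

    def test_invariant_under_segment_order(self, genome, expr):
        calls_fwd, _ = call_mutrs(genome.segments, genome.genes, expr)
        calls_rev, _ = call_mutrs(list(reversed(genome.segments)), genome.genes, expr)
        key = lambda c: (c.segment_id, c.gene_id, c.side, c.gap)
        assert sorted(map(key, calls_fwd)) == sorted(map(key, calls_rev))

    def test_selection_is_anti_monotone_in_correlation(self, genome, expr):
        """Replacing a selected segment's profile with its ORF's (|cc| -> 1)
        removes it from the call set and no new segment appears."""
        calls, _ = call_mutrs(genome.segments, genome.genes, expr)
        victim = calls[0]
        perturbed = expr.values.copy()
        perturbed.loc[victim.segment_id] = expr.values.loc[victim.gene_id]
        # keep it sporulation-specific in shape: reuse another mutr-like profile
        from mutrscan import ExpressionMatrix
        donor = calls[1]
        perturbed.loc[victim.segment_id] = expr.values.loc[donor.segment_id]
        perturbed.loc[victim.gene_id] = (
            expr.values.loc[donor.segment_id] + 3.0)  # now strongly correlated
        expr2 = ExpressionMatrix(values=perturbed, samples=expr.samples)
        calls2, _ = call_mutrs(genome.segments, genome.genes, expr2)
        called2 = {c.segment_id for c in calls2}
        assert victim.segment_id not in called2
        assert called2 <= {c.segment_id for c in calls}
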