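"""Anchor chaining and coverage against brute-force enumeration."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syntfrag import (AnnotationSet, ChainParams, OrthologyMap,
                      build_anchors, chain_anchors, coverage,
                      identity_truth, orthology_from_truth)
from syntfrag.synteny import Anchor, merge_intervals

from conftest import toy_annotation, toy_genome
from _oracles import brute_force_blocks


def _pair_from_orders(order_a, order_b, orphans_b=()):
    """Two toy annotations + orthology from gene-name orders."""
    annot_a = AnnotationSet.from_records(
        [(f"A_{g}", "sa", 100 * i, 100 * i + 60, "+")
         for i, g in enumerate(order_a)])
    annot_b = AnnotationSet.from_records(
        [(f"B_{g}", "sb", 100 * i, 100 * i + 60, "+")
         for i, g in enumerate(order_b)])
    orth = OrthologyMap([(f"A_{g}", f"B_{g}") for g in order_a
                         if g in set(order_b) - set(orphans_b)])
    return annot_a, annot_b, orth


class TestBuildAnchors:
    def test_collinear_ranks(self):
        a, b, orth = _pair_from_orders("XYZ", "XYZ")
        groups = build_anchors(orth, a, b)
        anchors = groups[("sa", "sb")]
        assert [(x.index_a, x.index_b) for x in anchors] == [(0, 0), (1, 1), (2, 2)]

    def test_orphan_gene_consumes_a_rank(self):
        a, b, orth = _pair_from_orders("XZ", "XYZ", orphans_b="Y")
        anchors = build_anchors(orth, a, b)[("sa", "sb")]
        assert [(x.index_a, x.index_b) for x in anchors] == [(0, 0), (1, 2)]

    def test_empty_orthology(self):
        a, b, _ = _pair_from_orders("XY", "XY")
        assert build_anchors(OrthologyMap([]), a, b) == {}

    def test_missing_gene_named_in_error(self):
        a, b, _ = _pair_from_orders("XY", "XY")
        with pytest.raises(KeyError, match="A_Q"):
            build_anchors(OrthologyMap([("A_Q", "B_X")]), a, b)


class TestChainAnchors:
    def test_same_order_single_block(self):
        a, b, orth = _pair_from_orders("ABCDE", "ABCDE")
        blocks = chain_anchors(build_anchors(orth, a, b),
                               ChainParams(min_anchors=3))
        assert len(blocks) == 1
        assert blocks[0].orientation == "same" and blocks[0].score == 5

    def test_reversed_segment_is_one_inverted_block(self):
        a, b, orth = _pair_from_orders("ABCDE", "EDCBA")
        blocks = chain_anchors(build_anchors(orth, a, b),
                               ChainParams(min_anchors=3))
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted" and blocks[0].score == 5

    def test_oversized_gap_splits_blocks(self):
        # 12 orphan genes on A between two runs: the gap limit is exceeded
        order_a = list("ABC") + [f"o{i}" for i in range(12)] + list("DEF")
        a, b, orth = _pair_from_orders(order_a, "ABCDEF")
        blocks = chain_anchors(build_anchors(orth, a, b),
                               ChainParams(min_anchors=3, max_gap_genes=10))
        assert len(blocks) == 2
        assert sorted(b.score for b in blocks) == [3, 3]

    def test_gap_within_limit_is_tolerated(self):
        order_a = list("ABC") + [f"o{i}" for i in range(10)] + list("DEF")
        a, b, orth = _pair_from_orders(order_a, "ABCDEF")
        blocks = chain_anchors(build_anchors(orth, a, b),
                               ChainParams(min_anchors=3, max_gap_genes=10))
        assert len(blocks) == 1 and blocks[0].score == 6

    @given(st.integers(0, 100_000))
    @settings(max_examples=150)
    def test_matches_exhaustive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        perm = rng.permutation(n)
        # random subset of anchors with random rank gaps on both sides
        ia = np.cumsum(rng.integers(1, 5, size=n))
        ib_order = np.cumsum(rng.integers(1, 5, size=n))
        anchors = [
            Anchor(f"a{i}", f"b{i}", "sa", "sb",
                   int(ia[i]), int(ib_order[perm[i]]),
                   100 * int(ia[i]), 100 * int(ia[i]) + 50,
                   100 * int(ib_order[perm[i]]),
                   100 * int(ib_order[perm[i]]) + 50)
            for i in range(n)
        ]
        params = ChainParams(min_anchors=2,
                             max_gap_genes=int(rng.integers(0, 6)))
        got = chain_anchors({("sa", "sb"): anchors}, params)
        expected = brute_force_blocks(anchors, params.min_anchors,
                                      params.max_gap_genes)
        assert len(got) == len(expected)
        exp_sorted = sorted(
            ([a.gene_a for a in chain],
             "same" if d == 1 else "inverted")
            for chain, d in expected)
        got_sorted = sorted(
            ([a.gene_a for a in b.anchors], b.orientation) for b in got)
        assert got_sorted == exp_sorted

    def test_anchors_assigned_to_at_most_one_block(self, evolved_pair):
        _, ref_annot, _, qry_annot, truth = evolved_pair
        orth = orthology_from_truth(truth, ref_annot, qry_annot)
        blocks = chain_anchors(build_anchors(orth, ref_annot, qry_annot),
                               ChainParams())
        seen = set()
        for blk in blocks:
            for a in blk.anchors:
                assert a.gene_a not in seen
                seen.add(a.gene_a)

    def test_parameter_monotonicity(self, evolved_pair):
        ref_genome, ref_annot, _, qry_annot, truth = evolved_pair
        orth = orthology_from_truth(truth, ref_annot, qry_annot)
        groups = build_anchors(orth, ref_annot, qry_annot)

        def cov(min_anchors, max_gap):
            blocks = chain_anchors(groups, ChainParams(min_anchors, max_gap))
            return coverage(blocks, ref_genome, "A").coverage

        assert cov(2, 10) >= cov(5, 10) >= cov(8, 10)
        assert cov(5, 15) >= cov(5, 10) >= cov(5, 2)

    def test_reversing_genome_b_flips_orientation_and_keeps_coverage(
            self, small_pair):
        genome, annot = small_pair
        truth = identity_truth(annot)
        orth = orthology_from_truth(truth, annot, annot)
        fwd = chain_anchors(build_anchors(orth, annot, annot), ChainParams())
        # reverse every scaffold's coordinate system on the B side
        rev_records = []
        for scaf, sub in annot.df.groupby("scaffold", sort=False):
            L = genome.scaffolds[scaf]
            for _, r in sub.iterrows():
                rev_records.append((r["gene_id"], scaf, L - r["end"],
                                    L - r["start"], r["strand"]))
        rev_annot = AnnotationSet.from_records(rev_records)
        rev = chain_anchors(build_anchors(orth, annot, rev_annot), ChainParams())
        assert all(b.orientation == "same" for b in fwd)
        assert all(b.orientation == "inverted" for b in rev)
        assert (coverage(fwd, genome, "A").coverage
                == coverage(rev, genome, "A").coverage)


class TestCoverage:
    def test_full_scaffold_block_is_100_percent(self):
        genome = toy_genome(200)
        block = _block("s1", 0, 200)
        assert coverage([block], genome, "A").coverage == 100.0

    def test_overlapping_blocks_are_merged(self):
        genome = toy_genome(200)
        blocks = [_block("s1", 0, 60), _block("s1", 40, 100)]
        assert coverage(blocks, genome, "A").coverage == 50.0

    def test_unknown_scaffold_errors(self):
        with pytest.raises(ValueError, match="mystery"):
            coverage([_block("mystery", 0, 10)], toy_genome(100), "A")

    def test_self_comparison_coverage_equals_gene_span_closed_form(
            self, small_pair):
        genome, annot = small_pair
        orth = orthology_from_truth(identity_truth(annot), annot, annot)
        blocks = chain_anchors(build_anchors(orth, annot, annot), ChainParams())
        expected = 100.0 * sum(e - s for s, e in annot.spans().values()) \
            / genome.total_length
        for side in "AB":
            assert coverage(blocks, genome, side).coverage == expected

    def test_merge_intervals(self):
        assert merge_intervals([(5, 9), (0, 3), (2, 4), (9, 12)]) \
            == [(0, 4), (5, 12)]


def _block(scaf, start, end):
    from syntfrag.synteny import SyntenyBlock
    return SyntenyBlock(scaf, start, end, "sb", start, end, "same", [])
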