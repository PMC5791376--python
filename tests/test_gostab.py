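"""Break-gene extraction, Fisher enrichment and rank stability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from syntfrag import (GOAnnotation, fisher_enrichment, genes_in_breaks,
                      rank_stability, simulate_go)
from syntfrag.synteny import SyntenyBlock

from conftest import toy_annotation, toy_genome
from _oracles import gene_block_overlap, hypergeom_tail_by_enumeration


def _block(scaf, start, end):
    return SyntenyBlock(scaf, start, end, scaf, start, end, "same", [])


class TestGenesInBreaks:
    def test_full_coverage_yields_empty_set(self):
        annot = toy_annotation([(100, 200), (300, 400)])
        out = genes_in_breaks([_block("s1", 0, 10_000)], annot,
                              toy_genome(), "A")
        assert out == set()

    def test_no_blocks_yields_all_genes(self):
        annot = toy_annotation([(100, 200), (300, 400)])
        assert genes_in_breaks([], annot, toy_genome(), "A") \
            == {"g1", "g2"}

    def test_edge_straddling_gene_is_excluded(self):
        annot = toy_annotation([(450, 550), (600, 700)])
        out = genes_in_breaks([_block("s1", 0, 500)], annot, toy_genome(), "A")
        assert out == {"g2"}  # g1 intersects the block edge

    @given(st.integers(0, 100_000))
    @settings(max_examples=30)
    def test_matches_interval_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [(int(i * 1_000 + rng.integers(0, 500)),
                  int(i * 1_000 + 500 + rng.integers(1, 400)))
                 for i in range(8)]
        blocks = [_block("s1", int(s), int(s) + int(rng.integers(50, 3_000)))
                  for s in rng.integers(0, 9_000, size=5)]
        annot = toy_annotation(genes)
        got = genes_in_breaks(blocks, annot, toy_genome(100_000), "A")
        intervals = [(b.start_a, b.end_a) for b in blocks]
        expected = {
            f"g{i + 1}" for i, gene in enumerate(genes)
            if not gene_block_overlap(gene, intervals)
        }
        assert got == expected


class TestFisherEnrichment:
    def test_perfectly_concentrated_term(self):
        universe = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(5)}
        go = GOAnnotation({g: {"GO:1"} for g in selected})
        res = fisher_enrichment(selected, universe, go)
        p = res.loc[res["term"] == "GO:1", "p"].iloc[0]
        from math import comb
        assert p == pytest.approx(1 / comb(20, 5))

    def test_proportional_term_is_not_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(5)}
        # term annotates 25% of selected and 25% of the rest
        members = {"g0", "g5", "g10", "g15"}
        go = GOAnnotation({g: {"GO:1"} for g in members})
        res = fisher_enrichment(selected, universe, go)
        assert res.loc[res["term"] == "GO:1", "p"].iloc[0] >= 0.5

    def test_small_terms_filtered_by_min_annotated(self):
        universe = {f"g{i}" for i in range(20)}
        go = GOAnnotation({"g0": {"GO:tiny"}, "g1": {"GO:tiny"},
                           "g2": {"GO:big"}, "g3": {"GO:big"},
                           "g4": {"GO:big"}})
        res = fisher_enrichment({"g0", "g1"}, universe, go, min_annotated=3)
        assert "GO:tiny" not in set(res["term"])
        assert "GO:big" in set(res["term"])

    def test_empty_selected_set(self):
        res = fisher_enrichment(set(), {"g0"}, GOAnnotation({}))
        assert res.empty

    @pytest.mark.parametrize("N,K,n", [(20, 5, 5), (25, 8, 6), (15, 4, 7)])
    def test_p_equals_exhaustive_enumeration(self, N, K, n):
        universe = {f"g{i}" for i in range(N)}
        selected = {f"g{i}" for i in range(n)}
        go = GOAnnotation({f"g{i}": {"GO:1"} for i in range(K)})
        res = fisher_enrichment(selected, universe, go, min_annotated=1)
        k = len(selected & {f"g{i}" for i in range(K)})
        expected = hypergeom_tail_by_enumeration(k, N, K, n)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_never_below_raw_p(self, small_pair):
        _, annot = small_pair
        genes = sorted(annot.gene_ids)
        go = simulate_go(genes, n_terms=30, seed=4)
        selected = set(genes[:50])
        res = fisher_enrichment(selected, set(genes), go)
        assert (res["adj_p"] >= res["p"] - 1e-12).all()
        # fewer significant terms as the size filter rises
        n_sig = [
            (fisher_enrichment(selected, set(genes), go,
                               min_annotated=m)["adj_p"] < 0.01).sum()
            for m in (1, 3, 10)
        ]
        assert n_sig[0] >= n_sig[1] >= n_sig[2]

    def test_p_invariant_under_gene_relabelling(self):
        universe = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(6)}
        go = GOAnnotation({f"g{i}": {"GO:1"} for i in (0, 1, 2, 9, 12)})
        p1 = fisher_enrichment(selected, universe, go)["p"].iloc[0]
        relabel = {f"g{i}": f"h{99 - i}" for i in range(20)}
        go2 = GOAnnotation({relabel[g]: t for g, t in go.gene_terms.items()})
        p2 = fisher_enrichment({relabel[g] for g in selected},
                               {relabel[g] for g in universe}, go2)["p"].iloc[0]
        assert p1 == p2

    def test_dag_propagation_to_ancestors(self):
        go = GOAnnotation({"g0": {"GO:child"}},
                          parents={"GO:child": {"GO:parent"}})
        t2g = go.term_to_genes()
        assert t2g["GO:parent"] == {"g0"}

    def test_cyclic_dag_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            GOAnnotation({}, parents={"a": {"b"}, "b": {"a"}})


class TestRankStability:
    def _result(self, terms_with_p):
        df = pd.DataFrame(terms_with_p, columns=["term", "p"])
        df["adj_p"] = df["p"]
        df = df.sort_values(["p", "term"]).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def test_identical_replicates_are_diagonal_with_zero_flags(self):
        orig = self._result([(f"T{i}", i / 100) for i in range(15)])
        stab = rank_stability(orig, [orig] * 5, top_k=10)
        assert stab.is_diagonal()
        assert stab.n_flags == 0 and stab.rank_shifts == 0

    def test_consistent_dropout_is_counted_every_replicate(self):
        orig = self._result([(f"T{i}", i / 100) for i in range(15)])
        # rank-10 term T9 pushed out of the top 10 in every replicate
        rep = self._result([(f"T{i}", i / 100) for i in range(9)]
                           + [("T9", 0.5)]
                           + [(f"T{i}", (i - 5) / 100) for i in range(10, 15)])
        stab = rank_stability(orig, [rep] * 7, top_k=10)
        assert stab.dropouts["T9"] == 7
        assert stab.matrix.loc["T9", "out"] == 7

    def test_intruder_from_outside_top_100_is_flagged(self):
        orig = self._result([(f"T{i}", i / 1000) for i in range(120)])
        rep = self._result([("NEW", 0.0)]
                           + [(f"T{i}", (i + 1) / 1000) for i in range(120)])
        stab = rank_stability(orig, [rep], top_k=10)
        assert stab.intruders.get("NEW") == 1

    def test_row_counts_sum_to_n_replicates(self):
        orig = self._result([(f"T{i}", i / 100) for i in range(12)])
        reps = [orig] * 4
        stab = rank_stability(orig, reps, top_k=10)
        assert (stab.matrix.sum(axis=1) == 4).all()


def test_spiked_term_is_recovered_at_rank_one(small_pair):
    _, annot = small_pair
    genes = sorted(annot.gene_ids)
    special = set(genes[::7])
    go = simulate_go(genes, n_terms=40, seed=9, spiked_term="GO:spike",
                     spiked_genes=special)
    res = fisher_enrichment(special, set(genes), go)
    assert res.iloc[0]["term"] == "GO:spike"
    assert res.iloc[0]["rank"] == 1
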