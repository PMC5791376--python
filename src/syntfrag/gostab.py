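"""GO enrichment of synteny-break genes and its stability under
fragmentation replicates.

Enrichment is classic per-term one-sided Fisher (hypergeometric tail) with
Benjamini-Hochberg adjustment over all tested terms; ranks are assigned by
ascending p-value with lexicographic term-id tie-breaking so every ranking
is deterministic. Stability across fragmentation replicates is summarised
as an occurrence matrix: for each term in the original (un-fragmented)
top-k, how often it landed at each replicate rank 1..k or fell out of the
top k, plus flags for intruders (terms far outside the original ranking
that enter a replicate top-k), dropouts and rank shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import AnnotationSet, Genome
from .synteny import SyntenyBlock, block_intervals

OUT_BUCKET = "out"


@dataclass
class GOAnnotation:
    """Gene -> GO-term sets, with an optional is_a parent map.

    When parents are given, annotations are propagated to ancestors (the
    true-path rule) before any counting.
    """

    gene_terms: dict[str, set[str]]
    parents: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        if self.parents is not None:
            self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p in self.parents.get(t, ()):
                if state.get(p) == 1:
                    raise ValueError(f"is_a cycle through term {t!r}")
                if p not in state:
                    visit(p)
            state[t] = 2

        for t in list(self.parents):
            if t not in state:
                visit(t)

    def ancestors(self, term: str) -> set[str]:
        if self.parents is None:
            return set()
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        return out

    def term_to_genes(self) -> dict[str, set[str]]:
        """Term -> annotated genes, ancestors included when a DAG is given."""
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            closed = set(terms)
            if self.parents is not None:
                for t in terms:
                    closed |= self.ancestors(t)
            for t in closed:
                out.setdefault(t, set()).add(gene)
        return out


def genes_in_breaks(blocks: list[SyntenyBlock], annot: AnnotationSet,
                    genome: Genome, which: str = "B") -> set[str]:
    """Genes lying entirely outside every merged synteny-block interval.

    A gene that touches a block edge is *not* a break gene — any
    intersection with a block keeps it out of the break set.
    """
    annot.bounds_check(genome)
    merged = block_intervals(blocks, which)
    out: set[str] = set()
    for scaf, sub in annot.df.groupby("scaffold", sort=False):
        intervals = merged.get(scaf, [])
        starts = np.array([s for s, _ in intervals], dtype=np.int64)
        ends = np.array([e for _, e in intervals], dtype=np.int64)
        for gid, gs, ge in zip(sub["gene_id"], sub["start"], sub["end"]):
            i = int(np.searchsorted(starts, ge, side="left")) - 1
            # candidate interval is the last one starting before the gene end
            if i >= 0 and ends[i] > gs:
                continue  # intersects a block
            out.add(gid)
    return out


def fisher_enrichment(selected: set[str], universe: set[str],
                      go: GOAnnotation, min_annotated: int = 3) -> pd.DataFrame:
    """Per-term over-representation of ``selected`` within ``universe``.

    Terms annotating fewer than ``min_annotated`` universe genes are not
    tested. Columns: term, selected_in_term, selected_total,
    universe_in_term, universe_total, p, adj_p, rank.
    """
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    if min_annotated < 1:
        raise ValueError("min_annotated must be >= 1")
    if not selected:
        return pd.DataFrame(columns=[
            "term", "selected_in_term", "selected_total", "universe_in_term",
            "universe_total", "p", "adj_p", "rank"])
    term_genes = go.term_to_genes()
    N = len(universe)
    n = len(selected)
    rows = []
    for term in sorted(term_genes):
        in_universe = term_genes[term] & universe
        K = len(in_universe)
        if K < min_annotated:
            continue
        k = len(in_universe & selected)
        # one-sided Fisher for over-representation == hypergeometric tail
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, p))
    if not rows:
        return pd.DataFrame(columns=[
            "term", "selected_in_term", "selected_total", "universe_in_term",
            "universe_total", "p", "adj_p", "rank"])
    df = pd.DataFrame(rows, columns=[
        "term", "selected_in_term", "selected_total", "universe_in_term",
        "universe_total", "p"])
    df["adj_p"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class StabilityResult:
    """Occurrence matrix + instability flags for the original top-k terms."""

    matrix: pd.DataFrame  # rows: original rank/term; columns: 1..k, "out"
    intruders: dict[str, int]  # term -> replicate count entering top-k
    dropouts: dict[str, int]  # original top-k term -> count absent from top-k
    rank_shifts: int  # (replicate, term) events retained at a different rank

    @property
    def n_flags(self) -> int:
        return len(self.intruders) + sum(1 for v in self.dropouts.values() if v)

    def is_diagonal(self) -> bool:
        """True when every original top-k term always kept its exact rank."""
        m = self.matrix.to_numpy()
        for i in range(len(m)):
            if m[i].sum() != m[i, i]:
                return False
        return True


def rank_stability(original: pd.DataFrame, replicates: list[pd.DataFrame],
                   top_k: int = 10, intruder_window: int = 100) -> StabilityResult:
    """Tally where each original top-k term lands across replicates.

    intruder_window: a replicate top-k term counts as an intruder when its
    original rank is beyond this window (or it was never ranked at all).
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    top = original.nsmallest(top_k, "rank").sort_values("rank")
    top_terms = list(top["term"])
    orig_rank = dict(zip(original["term"], original["rank"]))
    cols = [str(i) for i in range(1, top_k + 1)] + [OUT_BUCKET]
    matrix = pd.DataFrame(0, index=pd.Index(top_terms, name="term"), columns=cols)
    intruders: dict[str, int] = {}
    dropouts: dict[str, int] = {t: 0 for t in top_terms}
    rank_shifts = 0
    for rep in replicates:
        rep_rank = dict(zip(rep["term"], rep["rank"]))
        rep_top = {t: r for t, r in rep_rank.items() if r <= top_k}
        for t in top_terms:
            r = rep_top.get(t)
            if r is None:
                matrix.loc[t, OUT_BUCKET] += 1
                dropouts[t] += 1
            else:
                matrix.loc[t, str(int(r))] += 1
                if int(r) != int(orig_rank[t]):
                    rank_shifts += 1
        for t in rep_top:
            if orig_rank.get(t, np.inf) > intruder_window:
                intruders[t] = intruders.get(t, 0) + 1
    return StabilityResult(matrix, intruders, dropouts, rank_shifts)


def simulate_go(gene_ids, n_terms: int = 50, zipf_a: float = 1.8,
                base_size: int = 5, max_size_frac: float = 0.5,
                seed: int = 0, spiked_term: str | None = None,
                spiked_genes: set[str] | None = None) -> GOAnnotation:
    """Synthetic GO associations: term sizes Zipf-distributed, genes drawn
    uniformly per term; an optional spiked term is concentrated in a given
    gene set (e.g. deliberately un-syntenic genes) for recovery tests."""
    genes = list(gene_ids)
    rng = np.random.default_rng(seed)
    max_size = max(3, int(max_size_frac * len(genes)))
    gene_terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = min(max_size, base_size * int(rng.zipf(zipf_a)))
        members = rng.choice(len(genes), size=min(size, len(genes)),
                             replace=False)
        term = f"GO:{t + 1:07d}"
        for m in members:
            gene_terms.setdefault(genes[m], set()).add(term)
    if spiked_term is not None:
        for g in (spiked_genes or set()):
            gene_terms.setdefault(g, set()).add(spiked_term)
    return GOAnnotation(gene_terms)
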