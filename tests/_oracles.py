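"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration and direct
definitions, sharing no code path with the package internals.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def brute_force_n50(lengths) -> int:
    """Definition scan: largest observed length L with sum(x >= L) >= half."""
    lengths = list(lengths)
    total = sum(lengths)
    best = 0
    for cand in sorted(set(lengths)):
        if sum(x for x in lengths if x >= cand) >= total / 2:
            best = cand
    return best


def enumerate_chains(anchors, max_gap):
    """All forward-maximal monotone chains over (index_a, index_b) anchors.

    Each chain is a list of anchor objects, strictly increasing in index_a
    with steps <= max_gap+1 on A and uniformly monotone with steps of size
    1..max_gap+1 on B. Returns (chain, direction) pairs.
    """
    G = max_gap + 1
    anchors = sorted(anchors, key=lambda a: a.index_a)
    out = []

    def extend(chain, d):
        last = chain[-1]
        grew = False
        for nxt in anchors:
            if nxt.index_a <= last.index_a or nxt.index_a - last.index_a > G:
                continue
            step = (nxt.index_b - last.index_b) * d
            if 1 <= step <= G:
                extend(chain + [nxt], d)
                grew = True
        if not grew:
            out.append((chain, d))

    for a in anchors:
        extend([a], 1)
        extend([a], -1)
    return out


def brute_force_blocks(anchors, min_anchors, max_gap):
    """Greedy longest-first extraction over exhaustively enumerated chains.

    Selection among equally long chains is canonical: smallest index_a
    sequence, then `same` orientation first — the package's documented
    determinism contract. Returns a list of (anchor list, direction).
    """
    remaining = list(anchors)
    blocks = []
    while remaining:
        chains = enumerate_chains(remaining, max_gap)
        if not chains:
            break
        maxlen = max(len(c) for c, _ in chains)
        if maxlen < min_anchors:
            break
        cands = sorted(
            (tuple(a.index_a for a in c), 0 if d == 1 else 1, c, d)
            for c, d in chains if len(c) == maxlen
        )
        _, _, chain, d = cands[0]
        blocks.append((chain, d))
        taken = {id(a) for a in chain}
        remaining = [a for a in remaining if id(a) not in taken]
    return blocks


def brute_force_rbh(sim):
    """RBH by direct definition on a pandas DataFrame (rows A, cols B)."""
    pairs = []
    for a in sim.index:
        row = sim.loc[a]
        b = min(row.index[row == row.max()])
        col = sim[b]
        if min(col.index[col == col.max()]) == a:
            pairs.append((a, b))
    return sorted(pairs)


def hypergeom_tail_by_enumeration(k, N, K, n) -> float:
    """P(X >= k) for X = |selected ∩ term| by enumerating all n-subsets
    of an N-gene universe with K term genes. Exact rational arithmetic."""
    hits = 0
    universe = list(range(N))
    term = set(range(K))
    for subset in combinations(universe, n):
        if len(term.intersection(subset)) >= k:
            hits += 1
    return hits / comb(N, n)


def maximal_coordered_runs(perm):
    """Maximal runs of a permutation advancing by +1 or -1 consistently.

    perm[i] is the partner position of element i; returns (start, stop,
    direction) triples tiling range(len(perm)).
    """
    runs = []
    i = 0
    n = len(perm)
    while i < n:
        j = i + 1
        d = 0
        while j < n:
            step = perm[j] - perm[j - 1]
            if d == 0 and step in (1, -1):
                d = step
            elif step != d:
                break
            j += 1
        runs.append((i, j, d))
        i = j
    return runs


def gene_block_overlap(gene, intervals) -> bool:
    """Does [gene start, gene end) intersect any interval? Direct scan."""
    gs, ge = gene
    return any(s < ge and e > gs for s, e in intervals)
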