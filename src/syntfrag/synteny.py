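"""Anchor-based synteny block detection.

An anchor is a one-to-one ortholog pair placed at its gene-rank position
along each genome. Blocks are maximal chains of anchors that are strictly
increasing in rank on genome A and uniformly monotone (increasing = `same`,
decreasing = `inverted`) on genome B, where consecutive anchors may skip at
most ``max_gap_genes`` gene ranks on either genome — the skipped ranks are
genes without an ortholog assignment, the "gaps" tolerated inside a block.
Chains shorter than ``min_anchors`` are discarded; a block spans from the
start of its first anchor gene to the end of its last anchor gene on each
genome, and coverage is the merged block length over total assembly size.

Gaps are counted in skipped gene ranks (the DAGchainer convention) rather
than unaligned nucleotides. Overlapping chain candidates are resolved by
greedy longest-first extraction with a deterministic leftmost tie-break.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .model import AnnotationSet, Genome
from .orthology import OrthologyMap


@dataclass(frozen=True)
class Anchor:
    """One ortholog pair with its rank and coordinates on both genomes."""

    gene_a: str
    gene_b: str
    scaffold_a: str
    scaffold_b: str
    index_a: int  # gene rank along scaffold_a (every gene consumes a rank)
    index_b: int
    start_a: int
    end_a: int
    start_b: int
    end_b: int

    @property
    def midpoint_a(self) -> float:
        return (self.start_a + self.end_a) / 2.0

    @property
    def midpoint_b(self) -> float:
        return (self.start_b + self.end_b) / 2.0


@dataclass
class ChainParams:
    """Chaining thresholds; defaults mirror the common anchor-tool settings
    (at least five anchors per block, up to ten skipped genes per gap)."""

    min_anchors: int = 5
    max_gap_genes: int = 10

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap_genes < 0:
            raise ValueError("max_gap_genes must be >= 0")


@dataclass
class SyntenyBlock:
    scaffold_a: str
    start_a: int
    end_a: int
    scaffold_b: str
    start_b: int
    end_b: int
    orientation: str  # "same" | "inverted"
    anchors: list[Anchor] = field(repr=False, default_factory=list)

    @property
    def score(self) -> int:
        return len(self.anchors)


@dataclass
class CoverageReport:
    """Merged-block coverage of one genome side (percent of assembly size)."""

    side: str
    merged_length: int
    genome_size: int

    @property
    def coverage(self) -> float:
        return 100.0 * self.merged_length / self.genome_size


def build_anchors(orth: OrthologyMap, annot_a: AnnotationSet,
                  annot_b: AnnotationSet) -> dict[tuple[str, str], list[Anchor]]:
    """One anchor per ortholog pair, grouped by (scaffoldA, scaffoldB).

    Ranks are assigned by gene-start order over *all* genes of a scaffold,
    so genes without orthologs contribute no anchor but still widen the rank
    gap between neighbouring anchors.
    """
    ranks_a = annot_a.ranks()
    ranks_b = annot_b.ranks()
    coords_a = {r["gene_id"]: (int(r["start"]), int(r["end"]))
                for _, r in annot_a.df.iterrows()}
    coords_b = {r["gene_id"]: (int(r["start"]), int(r["end"]))
                for _, r in annot_b.df.iterrows()}
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a, b in orth.pairs:
        if a not in ranks_a:
            raise KeyError(f"orthology gene {a!r} missing from annotation A")
        if b not in ranks_b:
            raise KeyError(f"orthology gene {b!r} missing from annotation B")
        scaf_a, ia = ranks_a[a]
        scaf_b, ib = ranks_b[b]
        sa, ea = coords_a[a]
        sb, eb = coords_b[b]
        groups.setdefault((scaf_a, scaf_b), []).append(
            Anchor(a, b, scaf_a, scaf_b, ia, ib, sa, ea, sb, eb))
    for group in groups.values():
        group.sort(key=lambda x: x.index_a)
    return groups


def _canonical_longest_chain(anchors: list[Anchor],
                             max_gap: int) -> tuple[list[int], int] | None:
    """Longest valid chain among ``anchors`` (sorted by index_a).

    Returns (positions into ``anchors``, direction) for the canonical chain:
    maximum length, then lexicographically smallest index_a sequence, then
    `same` orientation. None when fewer than two anchors can chain.
    """
    n = len(anchors)
    if n == 0:
        return None
    G = max_gap + 1
    ia = [a.index_a for a in anchors]
    ib = [a.index_b for a in anchors]

    def successors(i: int, d: int) -> list[int]:
        out = []
        j = i + 1
        hi = bisect_right(ia, ia[i] + G)
        for j in range(i + 1, hi):
            step_b = (ib[j] - ib[i]) * d
            if 1 <= step_b <= G:
                out.append(j)
        return out

    # f[d][i]: longest chain starting at anchor i moving in direction d on B
    f = {1: [1] * n, -1: [1] * n}
    for i in range(n - 1, -1, -1):
        for d in (1, -1):
            best = 0
            for j in successors(i, d):
                if f[d][j] > best:
                    best = f[d][j]
            f[d][i] = 1 + best
    fmax = max(max(f[1]), max(f[-1]))
    if fmax < 2:
        return None

    def greedy(i: int, d: int) -> list[int]:
        chain = [i]
        need = f[d][i] - 1
        while need:
            nxt = min(j for j in successors(chain[-1], d) if f[d][j] == need)
            chain.append(nxt)
            need -= 1
        return chain

    candidates = []
    for d in (1, -1):
        starts = [i for i in range(n) if f[d][i] == fmax]
        if starts:
            i = min(starts, key=lambda i: ia[i])
            chain = greedy(i, d)
            candidates.append((tuple(ia[j] for j in chain), 0 if d == 1 else 1,
                               chain, d))
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, chain, d = candidates[0]
    return chain, d


def chain_anchors(groups: dict[tuple[str, str], list[Anchor]],
                  params: ChainParams) -> list[SyntenyBlock]:
    """Greedy longest-first chain extraction per scaffold pair.

    Anchors already consumed by a block are excluded from later chains, but
    their gene ranks still count toward gap distances (rank is a property of
    the gene order, not of chain membership).
    """
    blocks: list[SyntenyBlock] = []
    for key in sorted(groups):
        remaining = sorted(groups[key], key=lambda a: a.index_a)
        while True:
            found = _canonical_longest_chain(remaining, params.max_gap_genes)
            if found is None:
                break
            positions, d = found
            if len(positions) < params.min_anchors:
                break
            chosen = [remaining[i] for i in positions]
            blocks.append(_make_block(chosen, d))
            taken = set(positions)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]
    blocks.sort(key=lambda b: (b.scaffold_a, b.scaffold_b, b.start_a, b.start_b))
    return blocks


def _make_block(anchors: list[Anchor], direction: int) -> SyntenyBlock:
    return SyntenyBlock(
        scaffold_a=anchors[0].scaffold_a,
        start_a=min(a.start_a for a in anchors),
        end_a=max(a.end_a for a in anchors),
        scaffold_b=anchors[0].scaffold_b,
        start_b=min(a.start_b for a in anchors),
        end_b=max(a.end_b for a in anchors),
        orientation="same" if direction == 1 else "inverted",
        anchors=list(anchors),
    )


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coverage(blocks: list[SyntenyBlock], genome: Genome,
             which: str = "A") -> CoverageReport:
    """Merged synteny-block length over total assembly size, one side.

    Coverage is asymmetric between the two genomes because block spans
    differ on each side.
    """
    if which not in ("A", "B"):
        raise ValueError("which must be 'A' or 'B'")
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        scaf = b.scaffold_a if which == "A" else b.scaffold_b
        span = (b.start_a, b.end_a) if which == "A" else (b.start_b, b.end_b)
        if scaf not in genome:
            raise ValueError(f"block on unknown scaffold {scaf!r}")
        per_scaffold.setdefault(scaf, []).append(span)
    merged_length = sum(
        e - s
        for intervals in per_scaffold.values()
        for s, e in merge_intervals(intervals)
    )
    return CoverageReport(which, merged_length, genome.total_length)


def block_intervals(blocks: list[SyntenyBlock],
                    which: str = "A") -> dict[str, list[tuple[int, int]]]:
    """Merged block intervals per scaffold on one genome side."""
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        scaf = b.scaffold_a if which == "A" else b.scaffold_b
        span = (b.start_a, b.end_a) if which == "A" else (b.start_b, b.end_b)
        per_scaffold.setdefault(scaf, []).append(span)
    return {scaf: merge_intervals(iv) for scaf, iv in per_scaffold.items()}
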