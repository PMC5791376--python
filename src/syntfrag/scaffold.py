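"""Reference-guided scaffolding of a fragmented assembly, and measurement
of the false-collinearity artifact it creates.

Each fragment carrying at least one anchored gene is assigned to the
reference scaffold holding the majority of its anchors (at least half must
agree, which suppresses chimeric inter-chromosome joins), positioned at the
median reference coordinate of those anchors, and oriented by majority vote
over the direction of adjacent anchor pairs. Fragments are then tiled in
that order with fixed-length N gaps. Because placement follows the
*reference*, any true rearrangement of the query that fits inside single
fragments is silently undone: blocks detected against the reference come
out `same`-orientation and largely collinear even where the truth says
`inverted` — a pseudo-high-quality assembly with inflated contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fragment import n50
from .model import GENE_COLUMNS, AnnotationSet, Genome
from .orthology import OrthologyMap
from .simulate import TruthSet
from .synteny import SyntenyBlock


@dataclass
class Placement:
    fragment: str
    orientation: str  # "+" | "-"
    out_start: int
    out_end: int


@dataclass
class ScaffoldingPlan:
    """Ordered fragment placements per pseudochromosome, plus leftovers."""

    gap_len: int
    placements: dict[str, list[Placement]]  # pseudochromosome -> placements
    provenance: dict[str, str]  # pseudochromosome -> reference scaffold
    unplaced: list[str]
    fragment_lengths: dict[str, int]

    def pseudochromosome_lengths(self) -> dict[str, int]:
        out = {}
        for name, pls in self.placements.items():
            out[name] = pls[-1].out_end if pls else 0
        return out


@dataclass
class CollinearityReport:
    per_pair: pd.DataFrame  # scaffold_ref, pseudochromosome, n_blocks, n_inverted, rank_correlation
    n50_before: int
    n50_after: int
    orientation_losses: int
    n_truth_inversions: int
    false_joins: int
    n_adjacencies: int
    breakpoints_detected: int
    n_truth_breakpoints: int


def scaffold_by_reference(frag_genome: Genome, frag_annot: AnnotationSet,
                          ref_annot: AnnotationSet, orth: OrthologyMap,
                          gap_len: int = 100) -> tuple[Genome, AnnotationSet,
                                                       ScaffoldingPlan]:
    """Order and orient fragments along the reference; join with N gaps.

    ``orth`` maps reference genes (A side) to fragment genes (B side).
    Returns the scaffolded genome, its remapped annotation and the plan.
    """
    ref_pos = {r["gene_id"]: (r["scaffold"], (int(r["start"]) + int(r["end"])) / 2.0)
               for _, r in ref_annot.df.iterrows()}
    frag_of_gene = dict(zip(frag_annot.df["gene_id"], frag_annot.df["scaffold"]))

    # collect anchors per fragment: (frag coordinate, ref scaffold, ref coord)
    anchors: dict[str, list[tuple[int, str, float]]] = {}
    for ref_gene, q_gene in orth.pairs:
        if ref_gene not in ref_pos or q_gene not in frag_of_gene:
            continue
        frag = frag_of_gene[q_gene]
        row = frag_annot.df[frag_annot.df["gene_id"] == q_gene].iloc[0]
        anchors.setdefault(frag, []).append(
            (int(row["start"]), *ref_pos[ref_gene]))

    assigned: dict[str, list[tuple[float, str, str]]] = {}
    unplaced: list[str] = []
    for frag in frag_genome.scaffold_names:
        anc = sorted(anchors.get(frag, []))
        if not anc:
            unplaced.append(frag)
            continue
        counts: dict[str, int] = {}
        for _, scaf, _ in anc:
            counts[scaf] = counts.get(scaf, 0) + 1
        best_scaf = max(sorted(counts), key=counts.get)
        if counts[best_scaf] < 0.5 * len(anc):
            unplaced.append(frag)
            continue
        on_best = [(fp, rc) for fp, scaf, rc in anc if scaf == best_scaf]
        position = float(np.median([rc for _, rc in on_best]))
        # orientation: majority direction over adjacent anchor pairs
        up = sum(1 for (_, r1), (_, r2) in zip(on_best, on_best[1:]) if r2 > r1)
        down = sum(1 for (_, r1), (_, r2) in zip(on_best, on_best[1:]) if r2 < r1)
        orient = "-" if down > up else "+"
        assigned.setdefault(best_scaf, []).append((position, frag, orient))

    plan_placements: dict[str, list[Placement]] = {}
    provenance: dict[str, str] = {}
    scaffolds: dict[str, int] = {}
    sequences = {} if frag_genome.sequences is not None else None
    records: list[tuple] = []
    for ref_scaf in sorted(assigned):
        pseudo = f"{ref_scaf}_scaffolded"
        provenance[pseudo] = ref_scaf
        pls: list[Placement] = []
        pos = 0
        seq_parts: list[str] = []
        for position, frag, orient in sorted(assigned[ref_scaf]):
            flen = frag_genome.scaffolds[frag]
            if pls:
                pos += gap_len
                if sequences is not None:
                    seq_parts.append("N" * gap_len)
            start = pos
            end = pos + flen
            pls.append(Placement(frag, orient, start, end))
            if sequences is not None:
                s = frag_genome.sequences[frag]
                seq_parts.append(s if orient == "+" else _revcomp(s))
            # remap this fragment's genes
            sub = frag_annot.df[frag_annot.df["scaffold"] == frag]
            for gid, gs, ge, st in zip(sub["gene_id"], sub["start"],
                                       sub["end"], sub["strand"]):
                if orient == "+":
                    records.append((gid, pseudo, start + int(gs),
                                    start + int(ge), st))
                else:
                    records.append((gid, pseudo, start + flen - int(ge),
                                    start + flen - int(gs),
                                    "+" if st == "-" else "-"))
            pos = end
        scaffolds[pseudo] = pos
        if sequences is not None:
            sequences[pseudo] = "".join(seq_parts)
        plan_placements[pseudo] = pls

    plan = ScaffoldingPlan(
        gap_len=gap_len,
        placements=plan_placements,
        provenance=provenance,
        unplaced=sorted(unplaced),
        fragment_lengths=dict(frag_genome.scaffolds),
    )
    if not scaffolds:
        import warnings

        warnings.warn("no fragment carried an anchored gene; empty plan")
    genome = Genome(scaffolds, sequences)
    annot = AnnotationSet(pd.DataFrame(records, columns=GENE_COLUMNS),
                          validate=False)
    return genome, annot, plan


def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def _source_index(fragment: str) -> tuple[str, int] | None:
    """Parse '<scaffold>_frag<k>' provenance names."""
    if "_frag" not in fragment:
        return None
    scaf, _, k = fragment.rpartition("_frag")
    try:
        return scaf, int(k)
    except ValueError:
        return None


def assess_collinearity(blocks: list[SyntenyBlock], truth: TruthSet,
                        plan: ScaffoldingPlan,
                        ref_annot: AnnotationSet) -> CollinearityReport:
    """Compare blocks (reference vs scaffolded assembly) against the truth.

    Quantifies: N50 inflation from scaffolding; truth inversions whose
    anchors now sit in `same`-orientation blocks (orientation losses);
    plan adjacencies joining fragments that were never adjacent in the
    query (false joins); and truth rearrangement breakpoints still visible
    as block boundaries on the reference side.
    """
    # --- per scaffold-pair block stats + anchor-rank correlation ---
    rows = []
    for (sa, sb), group in _group_blocks(blocks).items():
        ranks_a = [a.index_a for b in group for a in b.anchors]
        ranks_b = [a.index_b for b in group for a in b.anchors]
        if len(ranks_a) > 1:
            rho = float(spearmanr(ranks_a, ranks_b).statistic)
        else:
            rho = float("nan")
        rows.append({
            "scaffold_ref": sa,
            "pseudochromosome": sb,
            "n_blocks": len(group),
            "n_inverted": sum(1 for b in group if b.orientation == "inverted"),
            "rank_correlation": rho,
        })
    per_pair = pd.DataFrame(rows)

    n50_before = n50(plan.fragment_lengths.values())
    lengths_after = list(plan.pseudochromosome_lengths().values())
    n50_after = n50(lengths_after) if lengths_after else 0

    # --- orientation losses over truth inversions ---
    ref_order = {scaf: list(sub["gene_id"])
                 for scaf, sub in ref_annot.df.groupby("scaffold", sort=False)}
    inversions = [(scaf, span) for kind, scaf, span in truth.applied_events
                  if kind == "inversion"]
    orientation_losses = 0
    for scaf, (i, j) in inversions:
        genes = set(ref_order[scaf][i:j])
        same = inv = 0
        for b in blocks:
            hits = sum(1 for a in b.anchors if a.gene_a in genes)
            if b.orientation == "same":
                same += hits
            else:
                inv += hits
        if same + inv > 0 and same > inv:
            orientation_losses += 1

    # --- false joins: plan adjacencies contradicting query adjacency ---
    false_joins = 0
    n_adjacencies = 0
    for pls in plan.placements.values():
        for p1, p2 in zip(pls, pls[1:]):
            n_adjacencies += 1
            s1, s2 = _source_index(p1.fragment), _source_index(p2.fragment)
            ok = (
                s1 is not None and s2 is not None
                and s1[0] == s2[0] and abs(s1[1] - s2[1]) == 1
            )
            if not ok:
                false_joins += 1

    # --- truth breakpoints still visible as block boundaries ---
    block_of_gene: dict[str, int] = {}
    for bi, b in enumerate(blocks):
        for a in b.anchors:
            block_of_gene[a.gene_a] = bi
    boundaries = set()
    for kind, scaf, (i, j) in truth.applied_events:
        if kind in ("inversion", "transposition"):
            for edge in (i, j):
                if 0 < edge < len(ref_order[scaf]):
                    boundaries.add((scaf, edge))
    detected = 0
    for scaf, edge in boundaries:
        left, right = ref_order[scaf][edge - 1], ref_order[scaf][edge]
        bl, br = block_of_gene.get(left), block_of_gene.get(right)
        if bl is None or br is None or bl != br:
            detected += 1

    return CollinearityReport(
        per_pair=per_pair,
        n50_before=int(n50_before),
        n50_after=int(n50_after),
        orientation_losses=orientation_losses,
        n_truth_inversions=len(inversions),
        false_joins=false_joins,
        n_adjacencies=n_adjacencies,
        breakpoints_detected=detected,
        n_truth_breakpoints=len(boundaries),
    )


def _group_blocks(blocks):
    groups: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for b in blocks:
        groups.setdefault((b.scaffold_a, b.scaffold_b), []).append(b)
    return groups
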