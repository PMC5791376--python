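"""Synthetic genome pairs with known orthology and ground-truth synteny.

The generator emulates the statistical structure of chromosome-scale
nematode assemblies: a handful of long scaffolds, gene densities around
200-290 genes/Mb, long-tailed intergenic gaps, one-to-one orthologs
interleaved with orphan genes, and intra-chromosomal rearrangements
(inversions, transpositions) between the two species of a pair.

No nucleotide-level evolution is modelled: anchor-based synteny detection
uses gene coordinates only, so sequence content is irrelevant to every
downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GENE_COLUMNS, AnnotationSet, Genome


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a log-normal with given
    arithmetic mean and standard deviation."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_lengths(rng: np.random.Generator, mean: float, sd: float,
                  n: int) -> np.ndarray:
    mu, sigma = _lognormal_params(mean, sd)
    return np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(np.int64)


@dataclass
class SimParams:
    """Reference-genome generator knobs.

    gene_density is genes per Mb; gene and intergenic lengths are the
    arithmetic mean/sd (bp) of log-normal draws truncated at 1 bp.
    """

    n_scaffolds: int = 1
    scaffold_length: int = 10_000_000
    gene_density: float = 200.0
    gene_length_mean: float = 2_000.0
    gene_length_sd: float = 1_500.0
    intergenic_length_mean: float = 3_000.0
    intergenic_length_sd: float = 3_000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        for name in ("scaffold_length", "gene_density", "gene_length_mean",
                     "gene_length_sd", "intergenic_length_mean",
                     "intergenic_length_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        n = round(self.gene_density * self.scaffold_length / 1e6)
        if n < 1:
            raise ValueError("gene_density * scaffold_length yields zero genes")
        if n * (self.gene_length_mean + self.intergenic_length_mean) > self.scaffold_length:
            raise ValueError(
                "gene density too high: mean gene + intergenic length "
                f"({self.gene_length_mean + self.intergenic_length_mean:.0f} bp "
                f"x {n} genes) cannot fit in {self.scaffold_length} bp"
            )

    @property
    def genes_per_scaffold(self) -> int:
        return round(self.gene_density * self.scaffold_length / 1e6)


#: Presets named after the two genera whose densities bracket the
#: N50-requirement recommendation (200 and 290 genes/Mb). Mean gene +
#: intergenic length is set to 1e6/density so the target density is realised.
PRESETS: dict[str, SimParams] = {
    "caenorhabditis_like": SimParams(
        gene_density=200.0, gene_length_mean=2_000.0, gene_length_sd=1_500.0,
        intergenic_length_mean=3_000.0, intergenic_length_sd=3_000.0,
    ),
    "strongyloides_like": SimParams(
        gene_density=290.0, gene_length_mean=1_500.0, gene_length_sd=1_000.0,
        intergenic_length_mean=1_948.0, intergenic_length_sd=2_000.0,
    ),
}


@dataclass
class EvoParams:
    """Rearrangement/turnover knobs applied when deriving the query species."""

    n_inversions: int = 0
    n_transpositions: int = 0
    ortholog_loss_fraction: float = 0.0
    gene_gain_fraction: float = 0.0
    rearrangement_span_mean: float = 5.0
    rearrangement_span_fixed: bool = False
    gene_gain_cluster_mean: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_inversions < 0 or self.n_transpositions < 0:
            raise ValueError("event counts must be >= 0")
        for name in ("ortholog_loss_fraction", "gene_gain_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rearrangement_span_mean < 2:
            raise ValueError("rearrangement_span_mean must be >= 2 genes")
        if self.gene_gain_cluster_mean < 1:
            raise ValueError("gene_gain_cluster_mean must be >= 1")


@dataclass
class TrueBlock:
    """A ground-truth syntenic segment (maximal co-ordered ortholog run)."""

    scaffold_a: str
    start_a: int
    end_a: int
    scaffold_b: str
    start_b: int
    end_b: int
    orientation: str  # "same" | "inverted"
    n_anchors: int


@dataclass
class TruthSet:
    """Ground truth produced alongside an evolved query genome."""

    orthology: list[tuple[str, str]]
    true_blocks: list[TrueBlock]
    applied_events: list[tuple[str, str, tuple[int, int]]]


def simulate_reference(params: SimParams) -> tuple[Genome, AnnotationSet]:
    """Lay genes left-to-right with log-normal lengths and intergenic gaps.

    Each scaffold receives exactly round(gene_density x length/1e6) genes.
    When a draw of lengths would overrun the scaffold, intergenic gaps are
    rescaled multiplicatively (floor 1 bp) so the layout fits; this preserves
    the gap distribution's shape while pinning the realised density.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.genes_per_scaffold
    scaffolds: dict[str, int] = {}
    records: list[tuple] = []
    for s in range(params.n_scaffolds):
        scaf = f"chr{s + 1}"
        L = params.scaffold_length
        glens = _draw_lengths(rng, params.gene_length_mean,
                              params.gene_length_sd, n)
        gaps = _draw_lengths(rng, params.intergenic_length_mean,
                             params.intergenic_length_sd, n)
        total = int(glens.sum() + gaps.sum())
        if total > L:
            budget = L - int(glens.sum()) - n  # keep >= 1 bp per gap
            if budget < 0:
                raise ValueError(
                    f"sampled gene lengths alone overflow scaffold {scaf!r}"
                )
            scale = budget / float(gaps.sum())
            gaps = np.maximum(1, np.floor(gaps * scale)).astype(np.int64)
        strands = rng.choice(["+", "-"], size=n)
        pos = 0
        for k in range(n):
            start = pos + int(gaps[k])
            end = start + int(glens[k])
            records.append((f"{scaf}.g{k + 1:05d}", scaf, start, end, strands[k]))
            pos = end
        scaffolds[scaf] = L
    return Genome(scaffolds), AnnotationSet(pd.DataFrame(records, columns=GENE_COLUMNS))


def _sample_disjoint_spans(rng: np.random.Generator, n_genes: int,
                           n_events: int, span_mean: float,
                           scaffold: str, fixed: bool = False) -> list[tuple[int, int]]:
    """Non-overlapping [i, j) gene-index spans.

    Span lengths are geometric with the stated mean (min 2 genes, so every
    event is detectable as an order break), or exactly round(span_mean)
    when ``fixed`` — useful for experiments that need events of a
    controlled physical size, e.g. inversions spanning whole fragments.
    """
    p = 1.0 / (span_mean - 1.0) if span_mean > 2 else 1.0
    spans: list[tuple[int, int]] = []
    taken = np.zeros(n_genes, dtype=bool)
    for _ in range(n_events):
        span = round(span_mean) if fixed else 1 + int(rng.geometric(p))
        if span > n_genes:
            raise ValueError(
                f"rearrangement span {span} exceeds gene count {n_genes} "
                f"on scaffold {scaffold!r}"
            )
        for _try in range(1000):
            i = int(rng.integers(0, n_genes - span + 1))
            if not taken[i:i + span].any():
                taken[i:i + span] = True
                spans.append((i, i + span))
                break
        else:
            raise ValueError(
                f"could not place a {span}-gene event on scaffold "
                f"{scaffold!r} without overlap"
            )
    return spans


def evolve_query(ref: Genome, annot: AnnotationSet,
                 evo: EvoParams) -> tuple[Genome, AnnotationSet, TruthSet]:
    """Derive a query species: rearrange gene order, lose/gain genes, relayout.

    The query genome is rebuilt from the mutated gene order: ortholog genes
    keep their reference length, intergenic gaps are bootstrap-resampled from
    the reference's observed gaps, so both genomes share length statistics
    without sharing coordinates.
    """
    evo.validate()
    rng = np.random.default_rng(evo.seed)
    events: list[tuple[str, str, tuple[int, int]]] = []

    # observed reference gaps (incl. leading gap per scaffold) for bootstrap
    ref_gaps: list[int] = []
    ref_glens: list[int] = []
    for scaf in ref.scaffold_names:
        sub = annot.genes_on(scaf)
        prev = 0
        for _, row in sub.iterrows():
            ref_gaps.append(max(1, int(row["start"]) - prev))
            ref_glens.append(int(row["end"]) - int(row["start"]))
            prev = int(row["end"])
    ref_gaps_arr = np.array(ref_gaps, dtype=np.int64)
    ref_glens_arr = np.array(ref_glens, dtype=np.int64)

    # per-scaffold gene order as mutable lists of (ref_id|None, length, strand)
    order: dict[str, list[dict]] = {}
    for scaf in ref.scaffold_names:
        sub = annot.genes_on(scaf)
        order[scaf] = [
            {"ref": gid, "len": int(e) - int(s), "strand": st, "inverted": False}
            for gid, s, e, st in zip(sub["gene_id"], sub["start"],
                                     sub["end"], sub["strand"])
        ]

    # --- rearrangements: sample disjoint spans per scaffold, then apply ---
    scaf_names = [s for s in ref.scaffold_names if len(order[s]) >= 2]
    weights = np.array([len(order[s]) for s in scaf_names], dtype=float)
    weights /= weights.sum()
    kinds = ["inversion"] * evo.n_inversions + ["transposition"] * evo.n_transpositions
    per_scaffold: dict[str, list[tuple[str, tuple[int, int]]]] = {s: [] for s in scaf_names}
    assignment = [scaf_names[int(rng.choice(len(scaf_names), p=weights))]
                  for _ in kinds]
    for scaf in scaf_names:
        idx = [i for i, s in enumerate(assignment) if s == scaf]
        if not idx:
            continue
        spans = _sample_disjoint_spans(
            rng, len(order[scaf]), len(idx), evo.rearrangement_span_mean,
            scaf, evo.rearrangement_span_fixed)
        for k, span in zip(idx, spans):
            per_scaffold[scaf].append((kinds[k], span))

    for scaf in scaf_names:
        evs = sorted(per_scaffold[scaf], key=lambda e: e[1][0])
        if not evs:
            continue
        # segment the order at event boundaries; disjointness makes this exact
        bounds = sorted({0, len(order[scaf])}
                        | {b for _, (i, j) in evs for b in (i, j)})
        segments = [order[scaf][bounds[k]:bounds[k + 1]]
                    for k in range(len(bounds) - 1)]
        seg_by_start = {bounds[k]: segments[k] for k in range(len(bounds) - 1)}
        # inversions reverse their segment in place (list identity kept)
        for kind, (i, j) in evs:
            if kind == "inversion":
                seg = seg_by_start[i]
                seg.reverse()
                for g in seg:
                    g["strand"] = "+" if g["strand"] == "-" else "-"
                    g["inverted"] = not g["inverted"]
            events.append((kind, scaf, (i, j)))
        # transpositions move their segment to a random other slot
        for kind, (i, j) in evs:
            if kind != "transposition":
                continue
            seg = seg_by_start[i]
            k = next(m for m, s in enumerate(segments) if s is seg)
            del segments[k]
            slot = int(rng.integers(0, len(segments) + 1))
            if slot == k:  # avoid the identity move
                slot = (slot + 1) % (len(segments) + 1)
            segments.insert(slot, seg)
        order[scaf] = [g for seg in segments for g in seg]

    # --- ortholog loss: drop genes from the query side ---
    for scaf in ref.scaffold_names:
        kept = []
        for pos, g in enumerate(order[scaf]):
            if rng.random() < evo.ortholog_loss_fraction:
                events.append(("loss", scaf, (pos, pos + 1)))
            else:
                kept.append(g)
        order[scaf] = kept

    # --- gene gain: insert orphan genes, singly or in clusters ---
    # clusters model lineage-specific family expansions; a cluster larger
    # than the chaining gap limit is what turns an insertion into a break
    n_total = sum(len(v) for v in order.values())
    n_gain = round(evo.gene_gain_fraction * n_total)
    gain_count = 0
    while gain_count < n_gain:
        if evo.gene_gain_cluster_mean > 1:
            cluster = int(rng.geometric(1.0 / evo.gene_gain_cluster_mean))
        else:
            cluster = 1
        cluster = min(cluster, n_gain - gain_count)
        scaf = ref.scaffold_names[int(rng.integers(0, len(ref.scaffold_names)))]
        slot = int(rng.integers(0, len(order[scaf]) + 1))
        for c in range(cluster):
            gain_count += 1
            glen = int(ref_glens_arr[int(rng.integers(0, len(ref_glens_arr)))])
            strand = str(rng.choice(["+", "-"]))
            order[scaf].insert(slot + c, {
                "ref": None, "len": glen, "strand": strand, "inverted": False,
                "orphan_id": f"q_orphan{gain_count:05d}"})
        events.append(("gain", scaf, (slot, slot + cluster)))

    # --- rebuild query genome with bootstrap-resampled intergenic gaps ---
    records: list[tuple] = []
    scaffolds: dict[str, int] = {}
    orthology: list[tuple[str, str]] = []
    for scaf in ref.scaffold_names:
        pos = 0
        for g in order[scaf]:
            gap = int(ref_gaps_arr[int(rng.integers(0, len(ref_gaps_arr)))])
            start = pos + gap
            end = start + g["len"]
            if g["ref"] is None:
                qid = g["orphan_id"]
            else:
                qid = "q_" + g["ref"]
                orthology.append((g["ref"], qid))
            records.append((qid, scaf, start, end, g["strand"]))
            pos = end
        tail = int(ref_gaps_arr[int(rng.integers(0, len(ref_gaps_arr)))])
        scaffolds[scaf] = max(pos + tail, 1)
    q_annot = AnnotationSet(pd.DataFrame(records, columns=GENE_COLUMNS))
    q_genome = Genome(scaffolds)

    truth = TruthSet(
        orthology=sorted(orthology),
        true_blocks=true_blocks_from_orders(annot, q_annot, orthology),
        applied_events=events,
    )
    return q_genome, q_annot, truth


def true_blocks_from_orders(annot_a: AnnotationSet, annot_b: AnnotationSet,
                            orthology: list[tuple[str, str]]) -> list[TrueBlock]:
    """Segment the ortholog complement into maximal co-ordered runs.

    Walking genome A's orthologs in order, a run extends while the partner's
    position in genome B's ortholog order advances by exactly +1 (same
    orientation) or -1 (inverted). Orphans and lost genes do not interrupt a
    run — they are gaps, not breaks. The resulting runs tile the ortholog
    complement and every rearrangement edge coincides with a run boundary.
    """
    a2b = dict(orthology)
    coords_a = {r["gene_id"]: (r["scaffold"], int(r["start"]), int(r["end"]))
                for _, r in annot_a.df.iterrows()}
    coords_b = {r["gene_id"]: (r["scaffold"], int(r["start"]), int(r["end"]))
                for _, r in annot_b.df.iterrows()}
    # genome B ortholog order index per scaffold
    b_orth_rank: dict[str, int] = {}
    b_scaf: dict[str, str] = {}
    b_ids = set(a2b.values())
    for scaf, sub in annot_b.df.groupby("scaffold", sort=False):
        r = 0
        for gid in sub["gene_id"]:
            if gid in b_ids:
                b_orth_rank[gid] = r
                b_scaf[gid] = scaf
                r += 1
    blocks: list[TrueBlock] = []
    for scaf, sub in annot_a.df.groupby("scaffold", sort=False):
        run: list[tuple[str, str]] = []
        direction = 0

        def flush():
            nonlocal run, direction
            if run:
                ga = [coords_a[a] for a, _ in run]
                gb = [coords_b[b] for _, b in run]
                blocks.append(TrueBlock(
                    scaffold_a=scaf,
                    start_a=min(c[1] for c in ga), end_a=max(c[2] for c in ga),
                    scaffold_b=gb[0][0],
                    start_b=min(c[1] for c in gb), end_b=max(c[2] for c in gb),
                    orientation="inverted" if direction == -1 else "same",
                    n_anchors=len(run),
                ))
            run, direction = [], 0

        for gid in sub["gene_id"]:
            if gid not in a2b:
                continue
            b = a2b[gid]
            if run:
                prev_b = run[-1][1]
                step = b_orth_rank[b] - b_orth_rank[prev_b]
                same_scaf = b_scaf[b] == b_scaf[prev_b]
                ok = same_scaf and (
                    (direction == 0 and step in (1, -1))
                    or (direction != 0 and step == direction)
                )
                if ok:
                    if direction == 0:
                        direction = step
                else:
                    flush()
            run.append((gid, b))
        flush()
    return blocks


def identity_truth(annot: AnnotationSet) -> TruthSet:
    """Truth for a self-comparison: identity orthology, one block/scaffold."""
    pairs = [(g, g) for g in annot.gene_ids]
    return TruthSet(
        orthology=pairs,
        true_blocks=true_blocks_from_orders(annot, annot, pairs),
        applied_events=[],
    )


def degrade_annotation(annot: AnnotationSet, missing_fraction: float,
                       seed: int) -> AnnotationSet:
    """Uniformly drop a fraction of genes, keeping the rest untouched.

    Models a lower-quality annotation of the same assembly.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    if missing_fraction == 0.0:
        return annot
    rng = np.random.default_rng(seed)
    keep = rng.random(len(annot)) >= missing_fraction
    return AnnotationSet(annot.df[keep], validate=False)
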