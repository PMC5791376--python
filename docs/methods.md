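# Methods

## Overview

`syntfrag` studies one question: how much synteny signal does assembly
fragmentation destroy, and what minimum contiguity (N50) keeps the damage
below a chosen error budget. Because real genome pairs confound
fragmentation with orthology-inference noise, annotation quality and tool
idiosyncrasies, everything here runs on simulated genome pairs with known
orthology and known rearrangement history, so every measured loss is
attributable.

## Synteny model

Anchors are one-to-one ortholog pairs. Each gene occupies a rank in the
start-order of its scaffold; genes without orthologs contribute no anchor
but still consume a rank, which is what makes them act as gaps. A chain is
valid when consecutive anchors advance 1..`max_gap_genes`+1 ranks on both
genomes, strictly increasing on genome A and uniformly monotone on genome
B; the B direction fixes the block orientation (`same`/`inverted`), and
mixed-orientation runs therefore split at the orientation change. Blocks
need `min_anchors` anchors (default 5; gap default 10 skipped genes).
Gaps are counted in skipped gene ranks, not unaligned nucleotides — the
two conventions disagree in practice, and the rank convention keeps the
core exactly testable against enumeration. A nucleotide-gap variant is
deliberately not implemented.

Overlapping chain candidates are resolved by greedy longest-first
extraction. Determinism is part of the contract: among equally long
chains the one with the lexicographically smallest A-rank sequence wins,
with `same` orientation breaking any remaining tie. The production
implementation is a windowed dynamic program (successors limited to the
gap window, O(n·gap) per pass); tests verify it against exhaustive
enumeration of all monotone chains on instances of ≤ 10 anchors, where
enumeration is feasible and the equality is checked chain-for-chain.
Anchors consumed by a block are excluded from later chains, but their
ranks still count toward gap distances — rank is a property of the gene
order, not of chain membership.

Coverage merges block intervals per scaffold (union, then summed) and
divides by total assembly size, separately per genome side; it is
asymmetric by construction. In a self-comparison the result has a closed
form — the per-scaffold span from first gene start to last gene end over
genome size — which the tests assert as exact float equality, since both
paths reduce to the same integer arithmetic.

## Genome simulation

`simulate_reference` lays genes left-to-right: per scaffold exactly
round(density × length/1e6) genes, lengths and intergenic gaps drawn
log-normal (truncated at 1 bp) with configurable arithmetic mean/sd. If a
draw would overrun the scaffold, the gaps are rescaled multiplicatively
(floor 1 bp), preserving the gap distribution's shape while pinning the
realised density; a density for which even the means cannot fit is
rejected up front. Two presets bracket the density contrast studied:

| preset | density | gene length | intergenic | rationale |
|---|---|---|---|---|
| `caenorhabditis_like` | 200 /Mb | 2000 ± 1500 bp | 3000 ± 3000 bp | mean gene+gap = 5000 = 1e6/200 |
| `strongyloides_like` | 290 /Mb | 1500 ± 1000 bp | 1948 ± 2000 bp | mean gene+gap = 3448 ≈ 1e6/290 |

The mean gene+intergenic budget is tied to the density so the target
density is realised exactly; the split between gene and gap length within
the budget follows the qualitative contrast between the two genera (the
denser genome has shorter genes and much shorter intergenic space).

`evolve_query` derives a second species: disjoint gene-index spans are
inverted (order reversed, strands flipped) or transposed (segment moved to
another position on the same scaffold); each gene is lost with probability
`ortholog_loss_fraction`; orphan genes are gained at random positions,
singly or — with `gene_gain_cluster_mean` > 1 — in geometric-sized
clusters that model lineage-specific family expansions. Clusters wider
than the gap limit are precisely the insertion-causes-break scenario; a
single orphan is just a gap. Rearrangement spans are geometric with a
configurable mean (minimum 2 genes, so every event is an order break), or
fixed-length when an experiment needs events of controlled physical size
(the scaffolding experiment uses 40-gene ≈ 200 kb fixed spans so each
inversion covers whole 100 kb fragments). The query genome is re-laid
from the mutated gene order: orthologs keep their reference gene length,
intergenic gaps are bootstrap-resampled from the reference's observed
gaps, so the two genomes share length statistics without sharing
coordinates.

The ground truth (`TruthSet`) records every applied event and segments the
ortholog complement into maximal co-ordered runs (partner position in the
other genome's ortholog order advancing consistently by +1 or −1); these
true blocks tile the orthologs, and every rearrangement edge coincides
with a run boundary. Tests check this against an independent run
enumeration on explicit permutations.

What the generator does **not** emulate: nucleotide-level evolution (the
anchor detector never reads sequence; FASTA output fills random ACGT),
paralogous families with sequence similarity, tandem arrays, scaffolding
gaps (N runs), repeat-driven non-uniform fragility, or the skewed
contig-length distributions of real assemblers. Passing tests therefore
demonstrate the *geometry* of fragmentation-induced synteny loss — anchor
loss at breaks, chains truncated below `min_anchors`, margin loss per
contig — not tool-specific scoring behaviour or repeat biology.

## Fragmentation

One uniform random phase offset per scaffold in [0, size), then fixed-size
tiling: an optional short leading piece, full-size fragments, a short
remainder; scaffolds at or below the target size pass through unchanged.
This realises an N50 equal to the fragment size for any scaffold ≥ a few
multiples of it, while different seeds break different places — which is
the entire source of replicate spread. Genes straddling a break are
dropped, not truncated: a split gene would not be annotated as a
one-to-one ortholog downstream, so dropping models anchor loss. Total
length is conserved exactly and checked on every call. Expected anchor
loss per replicate is ≈ n_genes × mean_gene_length / fragment_size.

## Error-rate sweep

`run_sweep` fragments only the query; the reference genome, annotation and
the coverage side stay fixed, so baseline − replicate coverage isolates
fragmentation damage. The baseline is measured, never assumed 100%.
Replicate seeds are base_seed + replicate index. Defaults follow the
study design (sizes 100 kb/200 kb/500 kb/1 Mb, 100 replicates); the test
suite and the acceptance script run 20 replicates on a single 10 Mb
chromosome, which keeps each sweep in the tens of seconds while leaving
the medians stable to well under a percentage point across seeds.
`required_n50` reads the smallest tested size whose median error meets a
threshold and reports `None` when none qualifies rather than
extrapolating beyond the tested grid.

## Orthology

The default pipeline restricts the simulation's ground-truth orthology to
surviving genes, isolating fragmentation effects from inference noise.
A reciprocal-best-hit implementation over an arbitrary similarity matrix
is provided for noise-injection experiments; ties are broken toward the
lexicographically smallest gene id on both sides, so a two-sided tie that
survives tie-breaking still pairs, and the output is always one-to-one.

## GO rank stability

Break genes are genes intersecting no merged block interval on their
genome side. Enrichment is classic per-term one-sided Fisher
(hypergeometric survival function) with Benjamini–Hochberg adjustment,
terms under `min_annotated` = 3 universe genes excluded, ranks assigned by
ascending p with lexicographic term-id tie-breaks. The graph-aware
decorrelation some GO tools apply is intentionally not reproduced: the
quantity under study is rank *instability* across fragmentation
replicates, which does not hinge on decorrelating parent/child terms.
The background universe defaults to all genes of the query annotation
(configurable); the synthetic GO generator draws Zipf-sized terms and can
spike one term into a chosen gene set for parameter-recovery tests.
Stability is an occurrence matrix (original top-k term × replicate rank
bucket 1..k plus "out"), with intruder flags (replicate top-k terms from
beyond the original top-100), dropout flags and rank-shift counts.

## Reference-guided scaffolding

Each fragment with anchors is assigned to the reference scaffold holding
the majority of them — at least half must agree or the fragment stays
unplaced, which suppresses chimeric inter-chromosome joins — positioned at
the median reference coordinate of its anchors, oriented by majority
direction over adjacent anchor pairs (ties keep the original
orientation), and tiled with fixed 100 bp N gaps (recorded in the plan so
coverage arithmetic stays exact; gaps count toward assembly size).
This mirrors what reference-guided placement does at the level exercised
here without re-implementing any particular tool's optimizer. The
assessment reports N50 before/after, inversions whose anchors return in
`same`-orientation blocks (orientation losses), plan adjacencies joining
fragments that were never adjacent in the query (false joins), and truth
breakpoints still visible as block boundaries. The false-collinearity
signature is asserted, not assumed: a collinear query round-trips to its
exact gene order with zero false joins, while fragment-spanning
inversions come back erased.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; GFF3 and TSV emission is
  1-based closed.
- All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline derives one seed per stage from a global seed via CRC32, kept
  below 2³¹. Equal config ⇒ byte-identical outputs (tested).
- Empty orthology yields no anchors and no blocks; a fragment size larger
  than every scaffold makes fragmentation the identity and the error rate
  exactly 0; an empty selected set yields an empty enrichment table; a
  zero-anchor assembly yields an empty scaffolding plan plus a warning.
- `n50` follows the definition "largest length ℓ with sum(lengths ≥ ℓ) ≥
  half the total" and rejects empty input.

## Known limitations

- Error rates here quantify detector-geometry loss under the rank-gap
  convention; absolute values for nucleotide-gap tools will differ.
- The scaffolding emulation has no gap-size estimation and no multi-map
  weighting; it reproduces the ordering/orienting artifact only.
- Median-error monotonicity in fragment size is a statistical property of
  the sweep, guaranteed only in expectation; adjacent sizes may tie at
  small replicate counts.
- The GO experiment's instability magnitude depends on how many break
  genes the baseline has; with a nearly perfect baseline (no insertions,
  no rearrangements) the break set is tiny and ranks are trivially
  stable.
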