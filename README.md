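# syntfrag

How badly does genome-assembly fragmentation corrupt synteny inference —
and how contiguous does an assembly have to be before synteny-based
conclusions can be trusted?

`syntfrag` answers this with a fully simulated, ground-truth-controlled
pipeline aimed at comparative genomicists who run anchor-based synteny
tools (DAGchainer, MCScanX, i-ADHoRe, SynChro and kin) on draft assemblies.
It simulates genome pairs with the statistical structure of chromosome-scale
nematode assemblies (gene densities around 200–290 genes/Mb, long-tailed
intergenic gaps, inversions/transpositions and gene turnover between
species), breaks the query assembly into fixed-size fragments at random
phases, re-detects synteny blocks, and measures what was lost. It also
reproduces two downstream failure modes: GO-enrichment rank instability of
synteny-break genes, and the false collinearity created when a fragmented
assembly is scaffolded against a related reference.

## The model

A **synteny block** is a maximal chain of **anchors** — one-to-one ortholog
pairs — strictly increasing in gene rank along genome A and uniformly
monotone (increasing = `same`, decreasing = `inverted`) along genome B.
Consecutive anchors may skip at most `max_gap_genes` gene ranks on either
genome (genes without orthologs are the tolerated gaps), and chains shorter
than `min_anchors` are discarded (defaults: 10 and 5, the common
anchor-tool settings). A block spans from its first anchor gene's start to
its last anchor gene's end on each genome, so

```
coverage (%) = 100 × Σ merged block lengths / assembly size
```

is asymmetric between the two genomes. Fragmenting the query at fragment
size *s* destroys anchors (genes straddling breaks are lost) and truncates
chains at contig ends; the **error rate** of a replicate is

```
error = coverage(reference vs intact query) − coverage(reference vs fragmented query)
```

with both coverages measured on the intact reference side. Sweeping *s*
over 100 kb–1 Mb with seeded replicates yields the error-rate-vs-N50 curve
from which a minimum N50 recommendation can be read off.

## Worked example

```python
from syntfrag import (PRESETS, ChainParams, SimParams, SweepConfig,
                      identity_truth, required_n50, run_sweep,
                      simulate_reference)

params = SimParams(**{**PRESETS["caenorhabditis_like"].__dict__,
                      "scaffold_length": 5_000_000, "seed": 7})
genome, annot = simulate_reference(params)
cfg = SweepConfig(fragment_sizes=(100_000, 500_000, 1_000_000),
                  n_replicates=10, base_seed=7,
                  chain_params=ChainParams(min_anchors=5, max_gap_genes=10))
report = run_sweep(genome, annot, genome, annot, identity_truth(annot), cfg)
print(f"baseline self-coverage: {report.baseline_coverage:.2f}%")
print(report.summary().to_string(index=False))
print("smallest fragment size with median error <= 5%:",
      required_n50(report, 5.0))
```

prints

```
baseline self-coverage: 98.30%
 fragment_size  median       q1       q3     mean
        100000 6.93622 6.561940 8.057180 7.402374
        500000 1.39252 1.145180 1.612015 1.371342
       1000000 0.68251 0.524175 0.815230 0.740992
smallest fragment size with median error <= 5%: 500000
```

Read: a 5 Mb chromosome at 200 genes/Mb compared against itself gives
98.3% synteny coverage (the margins outside the first/last gene of the
scaffold are never covered). Broken into 100 kb pieces, the median
replicate loses ~7 percentage points of coverage purely to fragmentation;
at 1 Mb pieces the loss is under 1 point. Of the tested sizes, 500 kb is
the smallest whose median error stays within 5 points.

The same machinery is scriptable from the shell:

```
syntfrag simulate --preset strongyloides_like --outdir sim/ --seed 1
syntfrag fragment --size 100000 --seed 2 --gff sim/reference.gff3 --outdir frag/
syntfrag detect --gff-a sim/reference.gff3 --gff-b frag/fragmented.gff3 \
                --orthology orth.tsv --out blocks.tsv
syntfrag run --config experiment.yaml     # sweep | go_stability | scaffold_pitfall
```

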