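"""Error rate of synteny identification across fragmentation replicates.

For each fragment size and replicate, the query assembly is broken at a
random phase, its annotation remapped, the ground-truth orthology restricted
to surviving genes, blocks re-detected, and coverage recomputed on the
intact reference side. The error rate of a replicate is the baseline
(un-fragmented) coverage minus the replicate coverage — the reference
assembly stays fixed in both measurements, so the difference isolates what
fragmentation of the query destroys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fragment import fragment_assembly, n50, remap_annotation
from .model import AnnotationSet, Genome
from .orthology import orthology_from_truth
from .simulate import TruthSet
from .synteny import ChainParams, build_anchors, chain_anchors, coverage


@dataclass
class SweepConfig:
    """Fragment sizes, replicate count and detector settings for one sweep."""

    fragment_sizes: tuple[int, ...] = (100_000, 200_000, 500_000, 1_000_000)
    n_replicates: int = 100
    base_seed: int = 0
    chain_params: ChainParams = field(default_factory=ChainParams)

    def __post_init__(self) -> None:
        sizes = tuple(self.fragment_sizes)
        if not sizes or any(s <= 0 for s in sizes):
            raise ValueError("fragment sizes must be positive")
        if list(sizes) != sorted(sizes):
            raise ValueError("fragment sizes must be sorted ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.fragment_sizes = sizes


@dataclass
class SweepReport:
    """Replicate-resolved error rates indexed by fragment size."""

    baseline_coverage: float
    records: pd.DataFrame  # columns: fragment_size, replicate, coverage, error_rate, n50

    def summary(self) -> pd.DataFrame:
        """Median and quartiles of error rate per fragment size."""
        g = self.records.groupby("fragment_size")["error_rate"]
        out = g.agg(median="median",
                    q1=lambda x: x.quantile(0.25),
                    q3=lambda x: x.quantile(0.75),
                    mean="mean").reset_index()
        return out

    def median_error(self, fragment_size: int) -> float:
        sub = self.records[self.records["fragment_size"] == fragment_size]
        if sub.empty:
            raise KeyError(f"no replicates at fragment size {fragment_size}")
        return float(sub["error_rate"].median())


def error_rate(cov_baseline: float, cov_fragmented: float) -> float:
    """Baseline coverage minus fragmented coverage, in percentage points."""
    return cov_baseline - cov_fragmented


def run_sweep(ref_genome: Genome, ref_annot: AnnotationSet,
              qry_genome: Genome, qry_annot: AnnotationSet,
              truth: TruthSet, cfg: SweepConfig) -> SweepReport:
    """The fragmentation sweep: only the query is broken; the reference
    genome and annotation stay intact, and coverage is always measured on
    the reference side.

    Replicate seeds are ``base_seed + replicate index``, so a sweep is fully
    reproducible and replicates differ only in where the breaks fall.
    """
    base_orth = orthology_from_truth(truth, ref_annot, qry_annot)
    base_blocks = chain_anchors(
        build_anchors(base_orth, ref_annot, qry_annot), cfg.chain_params)
    baseline = coverage(base_blocks, ref_genome, "A").coverage

    rows = []
    for size in cfg.fragment_sizes:
        for rep in range(cfg.n_replicates):
            seed = cfg.base_seed + rep
            frag_genome, bmap = fragment_assembly(qry_genome, size, seed)
            frag_annot = remap_annotation(qry_annot, bmap)
            orth = orthology_from_truth(truth, ref_annot, frag_annot)
            blocks = chain_anchors(
                build_anchors(orth, ref_annot, frag_annot), cfg.chain_params)
            cov = coverage(blocks, ref_genome, "A").coverage
            rows.append({
                "fragment_size": size,
                "replicate": rep,
                "coverage": cov,
                "error_rate": error_rate(baseline, cov),
                "n50": n50(frag_genome.scaffolds.values()),
            })
    return SweepReport(baseline, pd.DataFrame(rows))


def required_n50(report: SweepReport, threshold: float) -> int | None:
    """Smallest tested fragment size whose median error rate meets the
    threshold; ``None`` when no tested size qualifies (threshold
    unreachable within the sweep)."""
    sizes = sorted(report.records["fragment_size"].unique())
    if len(sizes) < 2:
        raise ValueError("report must cover at least two fragment sizes")
    for size in sizes:
        if report.median_error(int(size)) <= threshold:
            return int(size)
    return None
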