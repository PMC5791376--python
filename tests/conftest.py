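from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from syntfrag import (AnnotationSet, EvoParams, Genome, SimParams,
                      evolve_query, simulate_reference)

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Two 1 Mb scaffolds at 200 genes/Mb — 400 genes, fast everywhere."""
    return SimParams(n_scaffolds=2, scaffold_length=1_000_000,
                     gene_density=200, gene_length_mean=2_000,
                     gene_length_sd=1_500, intergenic_length_mean=3_000,
                     intergenic_length_sd=3_000, seed=11)


@pytest.fixture(scope="session")
def small_pair(small_params):
    genome, annot = simulate_reference(small_params)
    return genome, annot


@pytest.fixture(scope="session")
def evolved_pair(small_pair):
    """Reference plus a rearranged query with known truth."""
    genome, annot = small_pair
    evo = EvoParams(n_inversions=4, n_transpositions=2,
                    ortholog_loss_fraction=0.05, gene_gain_fraction=0.05,
                    rearrangement_span_mean=6, seed=23)
    q_genome, q_annot, truth = evolve_query(genome, annot, evo)
    return genome, annot, q_genome, q_annot, truth


def toy_annotation(gene_positions, scaffold="s1", prefix="g"):
    """AnnotationSet from a list of (start, end) pairs on one scaffold."""
    return AnnotationSet.from_records([
        (f"{prefix}{i + 1}", scaffold, s, e, "+")
        for i, (s, e) in enumerate(gene_positions)
    ])


def toy_genome(length=10_000, scaffold="s1"):
    return Genome({scaffold: length})
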