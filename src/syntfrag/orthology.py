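"""One-to-one orthology: the source of synteny anchors.

Two routes are provided. The default pipeline restricts the simulation's
ground-truth orthology to the genes that survived fragmentation or
annotation degradation, which isolates contiguity effects from
orthology-inference noise. Reciprocal best hits (RBH) on a similarity
matrix is available for experiments that want to inject inference noise.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .model import AnnotationSet


class OrthologyMap:
    """A set of one-to-one (geneA, geneB) correspondences."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        pairs = sorted(pairs)
        a_seen: dict[str, str] = {}
        b_seen: dict[str, str] = {}
        for a, b in pairs:
            if a in a_seen or b in b_seen:
                raise ValueError(
                    f"orthology is not one-to-one at pair ({a!r}, {b!r})")
            a_seen[a] = b
            b_seen[b] = a
        self.pairs: list[tuple[str, str]] = pairs
        self.a_to_b = a_seen
        self.b_to_a = b_seen

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologyMap):
            return NotImplemented
        return self.pairs == other.pairs

    def restrict(self, genes_a: Iterable[str],
                 genes_b: Iterable[str]) -> "OrthologyMap":
        sa, sb = set(genes_a), set(genes_b)
        return OrthologyMap((a, b) for a, b in self.pairs
                            if a in sa and b in sb)

    def transpose(self) -> "OrthologyMap":
        return OrthologyMap((b, a) for a, b in self.pairs)


def orthology_from_truth(truth, annot_a: AnnotationSet,
                         annot_b: AnnotationSet) -> OrthologyMap:
    """Ground-truth pairs restricted to genes present on both sides."""
    return OrthologyMap(truth.orthology).restrict(annot_a.gene_ids,
                                                  annot_b.gene_ids)


def reciprocal_best_hits(sim: pd.DataFrame) -> OrthologyMap:
    """RBH on a similarity matrix (rows: genome A genes, columns: genome B).

    A pair (a, b) is kept iff b is a's best hit and a is b's best hit,
    with score ties broken toward the lexicographically smallest gene id on
    each side — so a two-sided tie that survives tie-breaking still pairs.
    """
    if sim.size == 0:
        return OrthologyMap([])
    if not np.isfinite(sim.to_numpy(dtype=float)).all():
        raise ValueError("similarity matrix contains non-finite scores")
    cols = np.array(sim.columns, dtype=object)
    rows = np.array(sim.index, dtype=object)
    m = sim.to_numpy(dtype=float)

    def best(values: np.ndarray, labels: np.ndarray) -> object:
        top = values == values.max()
        return min(labels[top])

    best_b = {a: best(m[i], cols) for i, a in enumerate(rows)}
    best_a = {b: best(m[:, j], rows) for j, b in enumerate(cols)}
    return OrthologyMap(
        (a, b) for a, b in best_b.items() if best_a[b] == a)
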