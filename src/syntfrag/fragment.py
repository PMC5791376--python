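"""Random fixed-size fragmentation of an assembly.

Each scaffold longer than the target size is broken by drawing one uniform
random phase offset in [0, fragment_size) and then tiling fixed-size pieces:
an optional short leading piece, full-size fragments, and an optional short
trailing remainder. Scaffolds at or below the target size pass through
unchanged. Re-running with different seeds breaks the assembly at different
places, which is what gives replicate sweeps their spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GENE_COLUMNS, AnnotationSet, Genome

import pandas as pd


@dataclass
class BreakMap:
    """Where each output fragment came from.

    segments maps every input scaffold (pass-through ones included) to an
    ordered list of (fragment id, source start, source end); the segments of
    one scaffold tile it exactly.
    """

    fragment_size: int
    seed: int
    segments: dict[str, list[tuple[str, int, int]]]

    def n_breaks(self) -> int:
        return sum(len(segs) - 1 for segs in self.segments.values())

    def fragment_lengths(self) -> list[int]:
        return [e - s for segs in self.segments.values() for _, s, e in segs]


def tile_scaffold(length: int, fragment_size: int, offset: int) -> list[tuple[int, int]]:
    """Cut points for one scaffold: [0, offset) if offset > 0, then
    consecutive fragment_size pieces, then the remainder."""
    if not 0 <= offset < fragment_size:
        raise ValueError("offset must be in [0, fragment_size)")
    cuts = [0]
    pos = offset if offset > 0 else fragment_size
    while pos < length:
        cuts.append(pos)
        pos += fragment_size
    cuts.append(length)
    return [(cuts[k], cuts[k + 1]) for k in range(len(cuts) - 1)]


def fragment_assembly(genome: Genome, fragment_size: int,
                      seed: int) -> tuple[Genome, BreakMap]:
    """Break every scaffold into fixed-size pieces at a random phase.

    Total length is conserved exactly; fragments are named
    ``<scaffold>_frag<k>`` in source order so provenance stays recoverable.
    """
    if fragment_size < 1:
        raise ValueError("fragment_size must be >= 1")
    rng = np.random.default_rng(seed)
    segments: dict[str, list[tuple[str, int, int]]] = {}
    scaffolds: dict[str, int] = {}
    sequences: dict[str, str] | None = {} if genome.sequences is not None else None
    for name, L in genome.scaffolds.items():
        if L <= fragment_size:
            segments[name] = [(name, 0, L)]
            scaffolds[name] = L
            if sequences is not None:
                sequences[name] = genome.sequences[name]
            continue
        offset = int(rng.integers(0, fragment_size))
        segs = []
        for k, (s, e) in enumerate(tile_scaffold(L, fragment_size, offset)):
            frag = f"{name}_frag{k + 1}"
            segs.append((frag, s, e))
            scaffolds[frag] = e - s
            if sequences is not None:
                sequences[frag] = genome.sequences[name][s:e]
        segments[name] = segs
    return Genome(scaffolds, sequences), BreakMap(fragment_size, seed, segments)


def remap_annotation(annot: AnnotationSet, break_map: BreakMap) -> AnnotationSet:
    """Project genes onto fragments; genes straddling a break are dropped.

    Dropping (rather than truncating) models anchor loss: a gene split
    across two contigs would not be annotated as a one-to-one ortholog.
    Retained genes keep their length exactly.
    """
    records = []
    for scaf, sub in annot.df.groupby("scaffold", sort=False):
        if scaf not in break_map.segments:
            raise ValueError(f"annotation references unknown scaffold {scaf!r}")
        segs = break_map.segments[scaf]
        seg_starts = np.array([s for _, s, _ in segs])
        for gid, start, end, strand in zip(sub["gene_id"], sub["start"],
                                           sub["end"], sub["strand"]):
            i = int(np.searchsorted(seg_starts, start, side="right")) - 1
            frag, fs, fe = segs[i]
            if end <= fe:  # fully contained
                records.append((gid, frag, int(start) - fs, int(end) - fs, strand))
            # else: straddles a break -> dropped
    return AnnotationSet(pd.DataFrame(records, columns=GENE_COLUMNS),
                         validate=False)


def n50(lengths) -> int:
    """Largest length L such that sequences of length >= L hold half the total."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("n50 of an empty length list is undefined")
    if (arr <= 0).any():
        raise ValueError("all lengths must be positive")
    arr = np.sort(arr)[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[int(np.argmax(cum >= half))])
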