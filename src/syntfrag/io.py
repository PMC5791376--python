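"""Reading and writing the interchange formats.

FASTA goes through Biopython, GFF3 reading through gffutils; everything else
is plain TSV via pandas. Internal coordinates are 0-based half-open and are
converted to 1-based closed on GFF3/TSV emission.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GENE_COLUMNS, AnnotationSet, Genome

BLOCK_COLUMNS = [
    "scaffold_a", "start_a", "end_a",
    "scaffold_b", "start_b", "end_b",
    "orientation", "n_anchors",
]


def write_fasta(genome: Genome, path: str | Path, seed: int | None = None) -> None:
    """Write genome sequences; random ACGT fill for sequence-less genomes."""
    rng = np.random.default_rng(seed)
    records = []
    for name, length in genome.scaffolds.items():
        if genome.sequences is not None and name in genome.sequences:
            seq = genome.sequences[name]
        else:
            seq = "".join(rng.choice(list("ACGT"), size=length))
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Genome:
    scaffolds: dict[str, int] = {}
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        scaffolds[rec.id] = len(rec.seq)
        sequences[rec.id] = str(rec.seq)
    return Genome(scaffolds, sequences)


def write_gff3(annot: AnnotationSet, genome: Genome, path: str | Path,
               source: str = "syntfrag") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.scaffolds.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for _, row in annot.df.iterrows():
            fh.write(
                f"{row['scaffold']}\t{source}\tgene\t{row['start'] + 1}\t"
                f"{row['end']}\t.\t{row['strand']}\t.\tID={row['gene_id']}\n"
            )


def read_gff3(path: str | Path) -> AnnotationSet:
    """Load gene features from GFF3 (one representative isoform per locus)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    records = []
    for feat in db.features_of_type("gene"):
        records.append(
            (feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    return AnnotationSet(pd.DataFrame(records, columns=GENE_COLUMNS))


def write_orthology_tsv(pairs, path: str | Path) -> None:
    pd.DataFrame(sorted(pairs)).to_csv(path, sep="\t", header=False, index=False)


def read_orthology_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"],
                     dtype=str)
    return list(df.itertuples(index=False, name=None))


def write_blocks_tsv(blocks, path: str | Path) -> None:
    """Blocks TSV, 1-based closed coordinates (GFF3 convention)."""
    rows = []
    for b in blocks:
        rows.append((
            b.scaffold_a, b.start_a + 1, b.end_a,
            b.scaffold_b, b.start_b + 1, b.end_b,
            b.orientation, len(b.anchors),
        ))
    pd.DataFrame(rows, columns=BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_blocks_tsv(path: str | Path) -> pd.DataFrame:
    """Blocks table with coordinates converted back to 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    df["start_a"] -= 1
    df["start_b"] -= 1
    return df


def write_breakmap_tsv(break_map, path: str | Path) -> None:
    """AGP-like table: fragment, source scaffold, source start, source end."""
    rows = []
    for scaf, segs in break_map.segments.items():
        for frag_id, s, e in segs:
            rows.append((frag_id, scaf, s + 1, e))
    pd.DataFrame(
        rows, columns=["fragment", "source_scaffold", "source_start", "source_end"]
    ).to_csv(path, sep="\t", index=False)


def write_go_tsv(go, path: str | Path) -> None:
    rows = [(g, t) for g, terms in sorted(go.gene_terms.items())
            for t in sorted(terms)]
    pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(
        path, sep="\t", index=False)


def read_go_tsv(path: str | Path, parents_path: str | Path | None = None):
    from .gostab import GOAnnotation

    df = pd.read_csv(path, sep="\t")
    gene_terms: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term"]):
        gene_terms.setdefault(str(g), set()).add(str(t))
    parents = None
    if parents_path is not None:
        pdf = pd.read_csv(parents_path, sep="\t")
        parents = {}
        for c, p in zip(pdf.iloc[:, 0], pdf.iloc[:, 1]):
            parents.setdefault(str(c), set()).add(str(p))
    return GOAnnotation(gene_terms, parents)
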