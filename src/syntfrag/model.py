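"""Core in-memory containers: genomes and gene annotations.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based closed GFF3 convention happens only at (de)serialisation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "scaffold", "start", "end", "strand"]


@dataclass
class Genome:
    """An ordered collection of named scaffolds.

    Parameters
    ----------
    scaffolds
        Mapping of scaffold name to length in bp; insertion order is the
        assembly order.
    sequences
        Optional nucleotide sequences. When present, each sequence length
        must equal the declared scaffold length. Anchor-based synteny
        detection never inspects sequence, so most workflows leave this
        ``None`` and materialise random nucleotides only on FASTA export.
    """

    scaffolds: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, length in self.scaffolds.items():
            if length <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length {length}")
        if self.sequences is not None:
            for name, seq in self.sequences.items():
                if name not in self.scaffolds:
                    raise ValueError(f"sequence for unknown scaffold {name!r}")
                if len(seq) != self.scaffolds[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{self.scaffolds[name]} for scaffold {name!r}"
                    )

    @property
    def total_length(self) -> int:
        return sum(self.scaffolds.values())

    @property
    def scaffold_names(self) -> list[str]:
        return list(self.scaffolds)

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __len__(self) -> int:
        return len(self.scaffolds)


class AnnotationSet:
    """Protein-coding gene models, one representative isoform per locus.

    Wraps a :class:`pandas.DataFrame` with columns ``gene_id``, ``scaffold``,
    ``start``, ``end``, ``strand`` sorted by (scaffold, start). Gene ids are
    unique; intervals on a scaffold never overlap.
    """

    def __init__(self, genes: pd.DataFrame, *, validate: bool = True):
        missing = [c for c in GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        df = genes.loc[:, GENE_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df = df.sort_values(["scaffold", "start"], kind="stable").reset_index(drop=True)
        self.df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if (self.df["end"] <= self.df["start"]).any():
            bad = self.df.loc[self.df["end"] <= self.df["start"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad!r} has non-positive length")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        for scaf, sub in self.df.groupby("scaffold", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if len(sub) > 1 and (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping genes on {scaf!r}: "
                    f"{sub['gene_id'].iloc[i]!r} and {sub['gene_id'].iloc[i + 1]!r}"
                )

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "AnnotationSet":
        """Build from an iterable of (gene_id, scaffold, start, end, strand)."""
        return cls(pd.DataFrame(list(records), columns=GENE_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.df["gene_id"])

    def genes_on(self, scaffold: str) -> pd.DataFrame:
        """Genes on one scaffold, sorted by start."""
        return self.df[self.df["scaffold"] == scaffold]

    def subset(self, gene_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(gene_ids)
        return AnnotationSet(self.df[self.df["gene_id"].isin(keep)], validate=False)

    def ranks(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (scaffold, rank) with rank = start-order index per scaffold.

        Every gene consumes a rank, whether or not it has an ortholog — this
        is what makes orphan genes act as chaining gaps downstream.
        """
        out: dict[str, tuple[str, int]] = {}
        for scaf, sub in self.df.groupby("scaffold", sort=False):
            for rank, gid in enumerate(sub["gene_id"]):
                out[gid] = (scaf, rank)
        return out

    def spans(self) -> dict[str, tuple[int, int]]:
        """Per scaffold, (first gene start, last gene end)."""
        g = self.df.groupby("scaffold", sort=False)
        return {
            scaf: (int(sub["start"].min()), int(sub["end"].max()))
            for scaf, sub in g
        }

    def bounds_check(self, genome: Genome) -> None:
        """Raise if any gene exceeds its scaffold or names an unknown one."""
        for _, row in self.df.iterrows():
            if row["scaffold"] not in genome:
                raise ValueError(
                    f"gene {row['gene_id']!r} on unknown scaffold {row['scaffold']!r}"
                )
            if row["end"] > genome.scaffolds[row["scaffold"]]:
                raise ValueError(
                    f"gene {row['gene_id']!r} exceeds scaffold bound"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.df.equals(other.df)
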