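"""Gene annotation container with BED12 round-tripping.

Coordinates are 0-based half-open throughout.  The TSS of a ``+``-strand
gene is its ``start``; of a ``-``-strand gene, ``end - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneAnnotation:
    """Per-gene annotation: location, strand, exon structure.

    ``table`` has one row per gene with columns ``gene_id``, ``chrom``,
    ``start``, ``end``, ``strand``, ``exon_starts``, ``exon_ends`` (absolute
    coordinates, lists), ``tx_length`` (sum of exon lengths, bp).
    """

    table: pd.DataFrame
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "chrom", "start", "end", "strand",
                    "exon_starts", "exon_ends", "tx_length"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        for row in t.itertuples():
            starts, ends = row.exon_starts, row.exon_ends
            if len(starts) != len(ends) or len(starts) == 0:
                raise ValueError(f"{row.gene_id}: malformed exon lists")
            lengths = [e - s for s, e in zip(starts, ends)]
            if any(l <= 0 for l in lengths):
                raise ValueError(f"{row.gene_id}: empty or inverted exon")
            if starts[0] < row.start or ends[-1] > row.end:
                raise ValueError(f"{row.gene_id}: exon outside gene body")
            if any(starts[i + 1] < ends[i] for i in range(len(starts) - 1)):
                raise ValueError(f"{row.gene_id}: overlapping exons")
            if sum(lengths) != row.tx_length:
                raise ValueError(f"{row.gene_id}: tx_length != sum of exons")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)

    def tss(self) -> pd.Series:
        """Strand-aware TSS position per gene (0-based)."""
        t = self.table
        pos = np.where(t["strand"] == "+", t["start"], t["end"] - 1)
        return pd.Series(pos, index=t["gene_id"].to_numpy(), name="tss")

    def to_bed12(self, path: str) -> None:
        with open(path, "w") as fh:
            for row in self.table.itertuples():
                starts = [s - row.start for s in row.exon_starts]
                sizes = [e - s for s, e in zip(row.exon_starts, row.exon_ends)]
                fields = [
                    row.chrom, row.start, row.end, row.gene_id, 0, row.strand,
                    row.start, row.end, "0,0,0", len(sizes),
                    ",".join(map(str, sizes)) + ",",
                    ",".join(map(str, starts)) + ",",
                ]
                fh.write("\t".join(map(str, fields)) + "\n")

    @classmethod
    def from_bed12(cls, path: str,
                   chrom_sizes: dict[str, int] | None = None) -> "GeneAnnotation":
        rows = []
        max_end: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exon_starts = [start + o for o in offsets]
                exon_ends = [s + sz for s, sz in zip(exon_starts, sizes)]
                rows.append(dict(gene_id=name, chrom=chrom, start=start,
                                 end=end, strand=strand,
                                 exon_starts=exon_starts, exon_ends=exon_ends,
                                 tx_length=sum(sizes)))
                max_end[chrom] = max(max_end.get(chrom, 0), end)
        if chrom_sizes is None:
            chrom_sizes = {c: e + 10_000 for c, e in max_end.items()}
        return cls(pd.DataFrame(rows), chrom_sizes)
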