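"""Species-of-origin assignment for reads mapped to a concatenated genome.

Sequencing reads from mouse nuclei transplanted into Xenopus oocytes are
aligned against a combined mouse + Xenopus background genome; reads are kept
for a species only when their primary alignment lands on that species'
contigs with mapping quality strictly above a threshold (default 13), which
operationalizes "exclusively mapped" — cross-genome multi-mappers receive
low MAPQ from the aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

ASSIGN_LOW_QUALITY = "discarded-low-quality"
ASSIGN_UNMAPPED = "discarded-unmapped"

DEFAULT_MAPQ_MIN = 13


@dataclass(frozen=True)
class AlignmentLite:
    """Minimal alignment record: enough to partition by species."""

    read_id: str
    contig: str | None  # None = unmapped
    mapq: int = 0
    is_secondary: bool = False
    is_supplementary: bool = False


@dataclass
class PartitionResult:
    """Per-read species assignment plus class tallies.

    ``assignments`` maps read id -> species label or one of the discard
    classes; ``counts`` tallies every class and sums to the number of
    primary input records.
    """

    assignments: dict[str, str]
    counts: dict[str, int]

    def reads_for(self, species: str) -> list[str]:
        return [r for r, a in self.assignments.items() if a == species]


def _validate_species_map(species_map: Mapping[str, str]) -> set[str]:
    species = set(species_map.values())
    if len(species) != 2:
        raise ValueError(f"species map must define exactly two species, "
                         f"got {sorted(species)}")
    return species


def partition_alignments(
    records: Iterable[AlignmentLite],
    species_map: Mapping[str, str],
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> PartitionResult:
    """Assign each read to a species or a discard class.

    A read is assigned to species S iff its primary alignment is on a
    contig of S and MAPQ > ``mapq_min`` (strict).  MAPQ <= ``mapq_min``
    discards as low-quality; unmapped reads are tallied separately.
    Secondary and supplementary records never create assignments.
    """
    species = _validate_species_map(species_map)
    assignments: dict[str, str] = {}
    counts: Counter[str] = Counter({s: 0 for s in species})
    counts[ASSIGN_LOW_QUALITY] = 0
    counts[ASSIGN_UNMAPPED] = 0
    for i, rec in enumerate(records):
        if rec.is_secondary or rec.is_supplementary:
            continue
        if rec.read_id in assignments:
            raise ValueError(f"record {i}: duplicate primary alignment for "
                             f"read {rec.read_id!r}")
        if rec.contig is None:
            assignments[rec.read_id] = ASSIGN_UNMAPPED
        elif rec.contig not in species_map:
            raise ValueError(f"record {i}: contig {rec.contig!r} absent from "
                             "species map")
        elif rec.mapq > mapq_min:
            assignments[rec.read_id] = species_map[rec.contig]
        else:
            assignments[rec.read_id] = ASSIGN_LOW_QUALITY
        counts[assignments[rec.read_id]] += 1
    return PartitionResult(assignments=assignments, counts=dict(counts))


def partition_frame(records: pd.DataFrame, species_map: Mapping[str, str],
                    mapq_min: int = DEFAULT_MAPQ_MIN) -> PartitionResult:
    """Partition a simulator-style DataFrame (``read_id``, ``contig``,
    ``mapq``, ``mapped``)."""
    lite = [
        AlignmentLite(read_id=r.read_id,
                      contig=r.contig if r.mapped else None,
                      mapq=int(r.mapq))
        for r in records.itertuples()
    ]
    return partition_alignments(lite, species_map, mapq_min)


def partition_sam(path: str, species_map: Mapping[str, str],
                  mapq_min: int = DEFAULT_MAPQ_MIN,
                  out_prefix: str | None = None) -> PartitionResult:
    """Partition a SAM/BAM file; optionally write per-species SAM files
    (``{out_prefix}.{species}.sam``) containing the assigned reads."""
    import pysam

    _validate_species_map(species_map)
    lite = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        header = fh.header.to_dict()
        records = list(fh)
    for rec in records:
        lite.append(AlignmentLite(
            read_id=rec.query_name,
            contig=None if rec.is_unmapped else rec.reference_name,
            mapq=rec.mapping_quality,
            is_secondary=rec.is_secondary,
            is_supplementary=rec.is_supplementary,
        ))
    result = partition_alignments(lite, species_map, mapq_min)
    if out_prefix is not None:
        for sp in set(species_map.values()):
            keep = {r for r, a in result.assignments.items() if a == sp}
            with pysam.AlignmentFile(f"{out_prefix}.{sp}.sam", "w",
                                     header=pysam.AlignmentHeader.from_dict(header)) as out:
                for rec in records:
                    if (rec.query_name in keep and not rec.is_secondary
                            and not rec.is_supplementary):
                        out.write(rec)
    return result


def summary_frame(result: PartitionResult) -> pd.DataFrame:
    """One-row-per-class summary table of the partition."""
    return pd.DataFrame(
        [{"class": k, "reads": v} for k, v in sorted(result.counts.items())]
    )


def load_species_map(path: str) -> dict[str, str]:
    """Read a two-column TSV (contig, species) into a species map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "species"])
    return dict(zip(df["contig"], df["species"]))
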