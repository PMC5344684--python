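"""Plain-text readers/writers for the pipeline's tabular formats."""

from __future__ import annotations

import pandas as pd

from reprosist.synthetic_data import SimTruth


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_methylation(meth: pd.DataFrame, path: str) -> None:
    meth.to_csv(path, sep="\t", index=False)


def read_methylation(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_detable(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_detable(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_alignments_sam(records: pd.DataFrame,
                         contig_lengths: dict[str, int], path: str,
                         read_length: int = 50) -> None:
    """Write simulator alignment records as a single-end SAM file."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
    }
    refs = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(path, "w",
                             header=pysam.AlignmentHeader.from_dict(header)) as out:
        for r in records.itertuples():
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = "N" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            if r.mapped:
                a.reference_id = refs[r.contig]
                a.reference_start = int(r.pos)
                a.mapping_quality = int(r.mapq)
                a.cigarstring = f"{read_length}M"
                a.flag = 0
            else:
                a.flag = 4
                a.reference_id = -1
                a.mapping_quality = 0
            out.write(a)


def write_truth(truth: SimTruth, prefix: str) -> None:
    """Truth sidecar TSVs: resistant genes + sensitivity signatures."""
    rows = [
        dict(gene_id=g,
             sensitivity=",".join(sorted(truth.sensitivity_signature.get(g, ()))))
        for g in sorted(truth.resistant_genes)
    ]
    pd.DataFrame(rows, columns=["gene_id", "sensitivity"]).to_csv(
        f"{prefix}.resistant_truth.tsv", sep="\t", index=False)
    if truth.species_of_read:
        pd.DataFrame(
            sorted(truth.species_of_read.items()),
            columns=["read_id", "species"],
        ).to_csv(f"{prefix}.species_truth.tsv", sep="\t", index=False)
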