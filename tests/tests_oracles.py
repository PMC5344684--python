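"""Naive brute-force reference implementations used as test oracles.

These intentionally trade speed for obviousness: per-read, per-gene scans
with no data structures, against which the vectorized implementations are
checked.
"""

from itertools import combinations

import numpy as np
import pandas as pd


def brute_counts(fragments, annotation):
    """O(reads x exons) exon-overlap read counting."""
    counts = {g: 0 for g in annotation.gene_ids}
    for chrom, start, end in fragments:
        for row in annotation.table.itertuples():
            if row.chrom != chrom:
                continue
            if any(start < e and s < end
                   for s, e in zip(row.exon_starts, row.exon_ends)):
                counts[row.gene_id] += 1
    return pd.Series(counts)


def brute_bins(reads, annotation, flank=5000, bin_size=200):
    """O(reads x genes) TSS window binning with strand orientation."""
    nbins = 2 * flank // bin_size
    tss = annotation.tss()
    info = annotation.table.set_index("gene_id")
    out = {}
    for g in annotation.gene_ids:
        v = np.zeros(nbins, dtype=int)
        t = int(tss.loc[g])
        for r in reads.itertuples():
            if r.chrom == info.loc[g, "chrom"] and t - flank <= r.pos < t + flank:
                v[(r.pos - (t - flank)) // bin_size] += 1
        if info.loc[g, "strand"] == "-":
            v = v[::-1]
        out[g] = v
    return pd.DataFrame(out).T


def brute_methylation_pct(meth, annotation, gene_set, upstream=3000,
                          threshold=0.95):
    """Naive pooled promoter-CpG scan."""
    tss = annotation.tss()
    info = annotation.table.set_index("gene_id")
    hits = total = 0
    for g in gene_set:
        t = int(tss.loc[g])
        if info.loc[g, "strand"] == "+":
            lo, hi = t - upstream, t
        else:
            lo, hi = t + 1, t + 1 + upstream
        for r in meth.itertuples():
            if r.chrom == info.loc[g, "chrom"] and lo <= r.pos < hi:
                total += 1
                hits += r.fraction > threshold
    return 100.0 * hits / total


def brute_venn(sets):
    """Per-element membership-bitmask tabulation of Venn regions."""
    names = list(sets)
    union = set().union(*sets.values())
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = sum(
                1 for e in union
                if {n for n in names if e in sets[n]} == set(combo))
    return regions
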