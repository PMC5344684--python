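"""TSS metaplots, promoter methylation summaries, and set-level tests.

ChIP reads are counted in 200 bp bins across a 10 kb window centred on
every TSS; bin vectors are summed over a gene set, normalized per gene and
per million mapped reads, and the paired input profile is subtracted.
Promoter methylation is summarized as the percentage of CpGs in 3 kb
strand-aware upstream windows exceeding 95% methylation.  Gene-set scores
are tested against a permutation null of same-size random sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from reprosist.annotation import GeneAnnotation


@dataclass
class Profile:
    """Gene-set TSS profile: one value per bin, 5'->3' in gene orientation.

    ``values`` has length 2*flank/bin_size; units are input-subtracted (or
    raw) reads per gene per million mapped reads.  ``offsets`` records each
    bin's start offset relative to the TSS before strand reorientation.
    """

    values: np.ndarray
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 2 * self.flank // self.bin_size:
            raise ValueError("profile length inconsistent with flank/bin")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank, self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


def tss_bin_counts(reads: pd.DataFrame, annotation: GeneAnnotation,
                   flank: int = 5000, bin_size: int = 200,
                   orient_by_strand: bool = True) -> pd.DataFrame:
    """Per-gene binned read counts around the TSS.

    ``reads`` needs columns ``chrom`` and ``pos`` (the 5' position; reads
    contribute at that single point).  The window is [TSS-flank, TSS+flank)
    half-open; a read falls in the bin containing its 5' position.  With
    ``orient_by_strand`` the vectors of minus-strand genes are reversed so
    bins run 5'->3' along the gene.
    """
    if bin_size > flank:
        raise ValueError("bin size cannot exceed the flank")
    if flank % bin_size:
        raise ValueError("flank must be divisible by bin size")
    nbins = 2 * flank // bin_size
    tss = annotation.tss()
    strands = annotation.table.set_index("gene_id")["strand"]
    chroms = annotation.table.set_index("gene_id")["chrom"]

    by_chrom = {c: np.sort(sub["pos"].to_numpy())
                for c, sub in reads.groupby("chrom")}
    out = np.zeros((len(annotation), nbins), dtype=int)
    for gi, g in enumerate(annotation.gene_ids):
        pos = by_chrom.get(chroms.loc[g])
        if pos is None or len(pos) == 0:
            continue
        t = int(tss.loc[g])
        lo, hi = t - flank, t + flank
        window = pos[np.searchsorted(pos, lo):np.searchsorted(pos, hi)]
        if len(window) == 0:
            continue
        binned = np.bincount((window - lo) // bin_size, minlength=nbins)
        if orient_by_strand and strands.loc[g] == "-":
            binned = binned[::-1]
        out[gi] = binned
    return pd.DataFrame(out, index=annotation.gene_ids,
                        columns=np.arange(-flank, flank, bin_size))


def metaplot_profile(bin_counts: pd.DataFrame, gene_set: set[str],
                     total_mapped_reads: int, flank: int = 5000,
                     bin_size: int = 200) -> Profile:
    """Gene-set metaplot: bin sums over the set, divided by set size and by
    total mapped reads in millions."""
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    missing = set(gene_set) - set(bin_counts.index)
    if missing:
        raise ValueError(f"genes without bin vectors: {sorted(missing)[:5]}")
    summed = bin_counts.loc[sorted(gene_set)].sum(axis=0).to_numpy(dtype=float)
    values = summed / len(gene_set) / (total_mapped_reads / 1e6)
    return Profile(values, flank=flank, bin_size=bin_size)


def subtract_input(ip: Profile, inp: Profile) -> Profile:
    """Paired-input subtraction; the result may be negative."""
    if ip.flank != inp.flank or ip.bin_size != inp.bin_size:
        raise ValueError("IP and input profiles use different binnings")
    return Profile(ip.values - inp.values, flank=ip.flank,
                   bin_size=ip.bin_size)


def promoter_methylation_pct(meth: pd.DataFrame, annotation: GeneAnnotation,
                             gene_set: set[str], upstream: int = 3000,
                             threshold: float = 0.95,
                             per_gene: bool = False) -> float:
    """Percentage of promoter CpGs above the methylation threshold.

    CpGs from ``meth`` (columns ``chrom``, ``pos``, ``fraction``) falling
    in strand-aware [TSS-upstream, TSS) windows of set members are pooled;
    the return value is 100 * #(fraction > threshold) / #pooled.  With
    ``per_gene`` the per-gene percentages are averaged instead of pooling.
    """
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    missing = set(gene_set) - set(annotation.gene_ids)
    if missing:
        raise ValueError(f"genes not annotated: {sorted(missing)[:5]}")
    tss = annotation.tss()
    info = annotation.table.set_index("gene_id")
    by_chrom = {c: sub.sort_values("pos") for c, sub in meth.groupby("chrom")}

    pooled_hits = 0
    pooled_total = 0
    per_gene_pcts = []
    for g in sorted(gene_set):
        t = int(tss.loc[g])
        if info.loc[g, "strand"] == "+":
            lo, hi = t - upstream, t
        else:
            lo, hi = t + 1, t + 1 + upstream
        sub = by_chrom.get(info.loc[g, "chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        frac = sub["fraction"].to_numpy()
        sel = slice(np.searchsorted(pos, lo), np.searchsorted(pos, hi))
        window = frac[sel]
        if len(window):
            hits = int((window > threshold).sum())
            pooled_hits += hits
            pooled_total += len(window)
            per_gene_pcts.append(100.0 * hits / len(window))
    if pooled_total == 0:
        raise ValueError("no CpGs fall in any promoter window")
    if per_gene:
        return float(np.mean(per_gene_pcts))
    return 100.0 * pooled_hits / pooled_total


def permutation_gene_set_test(scores: pd.Series, subset: set[str],
                              universe: set[str] | None = None,
                              n_permutations: int = 10_000,
                              statistic: str = "sum",
                              alternative: str = "two-sided",
                              seed: int = 0
                              ) -> tuple[float, np.ndarray, float]:
    """Gene-set score vs a null of same-size random sets.

    The observed statistic (sum or mean of ``scores`` over ``subset``) is
    compared with ``n_permutations`` uniform same-size draws without
    replacement from the universe.  The two-sided empirical p is the
    proportion of background draws at least as far from the background
    mean as the observed value; ``alternative`` may also be ``greater`` or
    ``less``.  Returns (observed, background array, p).
    """
    if universe is None:
        universe = set(scores.index)
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    if not universe <= set(scores.index):
        raise ValueError("universe contains unscored genes")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    agg = {"sum": np.sum, "mean": np.mean}[statistic]
    rng = np.random.default_rng(seed)
    uni = np.asarray(sorted(universe))
    vals = scores.loc[uni].to_numpy(dtype=float)
    k = len(subset)
    observed = float(agg(scores.loc[sorted(subset)].to_numpy(dtype=float)))
    if k == len(uni):
        background = np.full(n_permutations, observed)
    else:
        background = np.empty(n_permutations)
        for b in range(n_permutations):
            idx = rng.choice(len(uni), size=k, replace=False)
            background[b] = agg(vals[idx])
    center = background.mean()
    if alternative == "two-sided":
        extreme = np.abs(background - center) >= abs(observed - center)
    elif alternative == "greater":
        extreme = background >= observed
    elif alternative == "less":
        extreme = background <= observed
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return observed, background, float(extreme.mean())


def rank_sum_test(a, b, exact_max: int = 20) -> tuple[float, float]:
    """Mann-Whitney U (two-sided) with mid-rank ties.

    Exact enumeration for small tie-free samples, normal approximation
    with tie correction otherwise.  Returns (U of sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = ("exact" if max(len(a), len(b)) <= exact_max and not ties
              else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t_test(a, b) -> tuple[float, float]:
    """Welch two-sample t test (unequal variances, two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
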