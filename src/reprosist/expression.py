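"""Read counting, normalization, filtering, and differential expression.

Differential expression uses an exact conditional negative-binomial test:
under a common dispersion phi, the sum of counts in each group is
negative-binomial, and conditional on the two-group total the group-1 sum
follows a negative hypergeometric law that is free of the unknown mean.
At phi = 0 this reduces to the exact conditional binomial (Poisson) test.
Library sizes are equalized by scaling counts to the geometric-mean depth
before testing; the common dispersion is estimated by method of moments
across genes unless supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from reprosist.annotation import GeneAnnotation

LOGFC_PSEUDOCOUNT = 0.5  # normalized counts added to each group mean


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_gene_reads(fragments, annotation: GeneAnnotation) -> pd.Series:
    """Count reads per gene by exon overlap.

    ``fragments`` is an iterable of ``(chrom, start, end)`` half-open
    intervals.  A read increments a gene iff it overlaps >= 1 bp of any of
    the gene's exons; a read overlapping exons of k genes increments all k.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in annotation.table.itertuples():
        tree = trees.setdefault(row.chrom, IntervalTree())
        for s, e in zip(row.exon_starts, row.exon_ends):
            tree[s:e] = row.gene_id

    counts = pd.Series(0, index=annotation.gene_ids, dtype=int)
    for chrom, start, end in fragments:
        if end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        tree = trees.get(chrom)
        if tree is None:
            continue
        hit_genes = {iv.data for iv in tree.overlap(start, end)}
        for g in hit_genes:
            counts[g] += 1
    return counts


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def _check_depths(counts: pd.DataFrame) -> pd.Series:
    depths = counts.sum(axis=0)
    zero = depths[depths <= 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {list(zero.index)}")
    return depths


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million mapped reads; each column sums to 1e6."""
    depths = _check_depths(counts)
    return counts / depths * 1e6


def rpkm_normalize(counts: pd.DataFrame,
                   transcript_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    depths = _check_depths(counts)
    lengths = transcript_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:5])
        raise ValueError(f"missing transcript lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    return counts.div(depths / 1e6, axis=1).div(lengths / 1e3, axis=0)


def filter_expressed(counts: pd.DataFrame, group1: list[str],
                     group2: list[str], mode: str = "replicated",
                     transcript_lengths: pd.Series | None = None) -> set[str]:
    """Expression filter for a two-group comparison.

    ``replicated``: keep a gene iff CPM >= 1 in *all* samples of group 1 or
    in *all* samples of group 2.  ``unreplicated``: RPKM > 1 analogously
    (requires ``transcript_lengths``).
    """
    if not group1 or not group2:
        raise ValueError("exactly two non-empty groups required")
    if mode == "replicated":
        norm = cpm_normalize(counts[list(group1) + list(group2)])
        ok1 = (norm[group1] >= 1).all(axis=1)
        ok2 = (norm[group2] >= 1).all(axis=1)
    elif mode == "unreplicated":
        if transcript_lengths is None:
            raise ValueError("unreplicated mode requires transcript lengths")
        norm = rpkm_normalize(counts[list(group1) + list(group2)],
                              transcript_lengths)
        ok1 = (norm[group1] > 1).all(axis=1)
        ok2 = (norm[group2] > 1).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return set(counts.index[ok1 | ok2])


# ---------------------------------------------------------------------------
# exact conditional NB test
# ---------------------------------------------------------------------------

@dataclass
class DEParams:
    """Exact-test settings: ``dispersion=None`` estimates a common
    dispersion by method of moments; ``pseudocount`` enters only the logFC."""

    dispersion: float | None = None
    pseudocount: float = LOGFC_PSEUDOCOUNT
    metadata: dict = field(default_factory=dict)


def estimate_common_dispersion(adjusted: pd.DataFrame,
                               groups: list[list[str]]) -> float:
    """Method-of-moments common dispersion from depth-adjusted counts.

    For each gene and group with >= 2 samples, E[s^2] = mu + phi*mu^2; phi
    is estimated by pooling (s^2 - xbar) against (xbar^2 - s^2/n) over all
    genes and groups (the denominator correction debiases xbar^2).
    """
    num = 0.0
    den = 0.0
    for g in groups:
        if len(g) < 2:
            continue
        sub = adjusted[g].to_numpy(dtype=float)
        xbar = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += float((s2 - xbar).sum())
        den += float((xbar ** 2 - s2 / len(g)).clip(min=0.0).sum())
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _exact_conditional_pvalue(y1: int, s: int, n1: int, n2: int,
                              phi: float) -> float:
    """Two-sided exact p-value for the group-1 sum ``y1`` of ``s`` total
    counts split between n1 and n2 equal-depth samples.

    phi = 0: conditional law is Binomial(s, n1/(n1+n2)); phi > 0 with
    per-sample size r = 1/phi: negative hypergeometric with weights
    C(y+n1*r-1, y) * C(s-y+n2*r-1, s-y).  Two-sided p sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    if phi == 0:
        logp = (gammaln(s + 1) - gammaln(y + 1) - gammaln(s - y + 1)
                + y * np.log(n1 / (n1 + n2))
                + (s - y) * np.log(n2 / (n1 + n2)))
    else:
        r = 1.0 / phi
        logw = (gammaln(y + n1 * r) - gammaln(y + 1)
                + gammaln(s - y + n2 * r) - gammaln(s - y + 1))
        logp = logw - logsumexp(logw)
    obs = logp[y1]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(p, 1.0)


def nb_exact_de(counts: pd.DataFrame, group1: list[str], group2: list[str],
                params: DEParams | None = None) -> pd.DataFrame:
    """Exact conditional NB differential-expression test.

    Returns a DETable: one row per gene with ``logFC`` (log2 of group-2
    mean over group-1 mean, after depth adjustment and with a small
    pseudocount), ``pvalue``, ``fdr`` (Benjamini-Hochberg), ``mean1`` and
    ``mean2`` (depth-adjusted group means).  Orientation is recorded in
    ``result.attrs``.
    """
    params = params or DEParams()
    if not group1 or not group2:
        raise ValueError("both groups need >= 1 sample")
    sub = counts[list(group1) + list(group2)]
    depths = _check_depths(sub)

    # equalize depths: scale to the geometric-mean library size and round
    target = float(np.exp(np.log(depths).mean()))
    adjusted = sub * (target / depths)
    n1, n2 = len(group1), len(group2)

    phi = params.dispersion
    if phi is None:
        phi = estimate_common_dispersion(adjusted, [list(group1), list(group2)])

    a1 = adjusted[group1].to_numpy(dtype=float)
    a2 = adjusted[group2].to_numpy(dtype=float)
    y1 = np.rint(a1.sum(axis=1)).astype(np.int64)
    y2 = np.rint(a2.sum(axis=1)).astype(np.int64)

    pvals = np.array([
        _exact_conditional_pvalue(int(a), int(a + b), n1, n2, phi)
        for a, b in zip(y1, y2)
    ])
    mean1 = a1.mean(axis=1)
    mean2 = a2.mean(axis=1)
    pc = params.pseudocount
    logfc = np.log2((mean2 + pc) / (mean1 + pc))

    table = pd.DataFrame({
        "logFC": logfc,
        "pvalue": pvals,
        "fdr": bh_fdr(pvals),
        "mean1": mean1,
        "mean2": mean2,
    }, index=sub.index)
    table.attrs["orientation"] = "group2/group1"
    table.attrs["group1"] = list(group1)
    table.attrs["group2"] = list(group2)
    table.attrs["dispersion"] = phi
    table.attrs["dispersion_source"] = (
        "given" if params.dispersion is not None else "method-of-moments")
    table.attrs["fdr_method"] = "benjamini-hochberg"
    return table


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, fdr_max: float = 0.05,
            abs_logfc_min: float = 0.0) -> tuple[set, set]:
    """Threshold a DETable into (up, down) gene sets.

    A gene is called iff FDR < ``fdr_max`` and |logFC| > ``abs_logfc_min``
    (both strict); sign of logFC decides up vs down.
    """
    if fdr_max < 0 or abs_logfc_min < 0:
        raise ValueError("thresholds must be non-negative")
    sig = (table["fdr"] < fdr_max) & (table["logFC"].abs() > abs_logfc_min)
    up = set(table.index[sig & (table["logFC"] > 0)])
    down = set(table.index[sig & (table["logFC"] < 0)])
    return up, down


def fold_change_de_unreplicated(mean1: pd.Series, mean2: pd.Series,
                                abs_logfc_min: float = 1.0,
                                pseudocount: float = LOGFC_PSEUDOCOUNT
                                ) -> pd.DataFrame:
    """Unreplicated DE rule: called iff |log2(mean2/mean1)| > 1 (strict),
    with a pseudocount guarding zero means."""
    if (mean1 < 0).any() or (mean2 < 0).any():
        raise ValueError("means must be non-negative")
    logfc = np.log2((mean2 + pseudocount) / (mean1 + pseudocount))
    return pd.DataFrame({
        "logFC": logfc,
        "de": logfc.abs() > abs_logfc_min,
    })


def ma_table(table: pd.DataFrame, reference_rpkm: pd.Series,
             fdr_max: float = 0.05) -> pd.DataFrame:
    """MA-plot data: x = log2(RPKM + 1) of the reference expression,
    y = logFC, plus the DE flag.  One row per tested gene."""
    ref = reference_rpkm.reindex(table.index)
    if ref.isna().any():
        missing = list(ref[ref.isna()].index[:5])
        raise ValueError(f"missing reference expression, e.g. {missing}")
    return pd.DataFrame({
        "x": np.log2(ref + 1.0),
        "y": table["logFC"],
        "de": table["fdr"] < fdr_max,
    }, index=table.index)
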