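"""Resistant-gene calling, digital signatures, and combination effects.

A gene is resistant when the oocyte transcribes it significantly less from
MEF chromatin than from ES chromatin after nuclear transfer (FDR < 0.05 and
log2FC(MEF/ES) < 0).  Repeating the comparison under each chromatin-modifier
condition yields, per resistant gene, a binary "digital signature": 1 where
resistance is maintained, 0 where the treatment removed it.  Comparing
single treatments A and B with their combination AB classifies the combined
effect as synergistic, neutral, adverse, or insensitive.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


class ComboEffect(str, Enum):
    SYNERGISTIC = "synergistic"
    NEUTRAL = "neutral"
    ADVERSE = "adverse"
    INSENSITIVE = "insensitive"


def call_resistant(table: pd.DataFrame,
                   fdr_max: float = 0.05) -> tuple[set, set]:
    """Split a MEF/ES-oriented DETable into resistant sets.

    MEF-resistant: FDR < ``fdr_max`` and logFC(MEF/ES) < 0 (the oocyte
    under-transcribes the gene from MEF chromatin).  ES-resistant: FDR <
    ``fdr_max`` and logFC > 0.  The table must be oriented MEF over ES.
    """
    orientation = table.attrs.get("orientation")
    if orientation is not None and orientation not in ("MEF/ES", "group2/group1"):
        raise ValueError(f"unexpected orientation {orientation!r}; "
                         "expected a MEF-over-ES table")
    sig = table["fdr"] < fdr_max
    mef = set(table.index[sig & (table["logFC"] < 0)])
    es = set(table.index[sig & (table["logFC"] > 0)])
    return mef, es


def digital_signature(tables: Mapping[str, pd.DataFrame],
                      resistant_genes: set[str],
                      condition_order: list[str] | None = None,
                      fdr_max: float = 0.05) -> pd.DataFrame:
    """Binary resistance signature over conditions.

    ``tables`` maps condition label -> DETable oriented MEF/ES against the
    fixed untreated ES-NT reference.  Entry (gene, condition) is 1 iff
    logFC < 0 and FDR < ``fdr_max`` in that condition's table, else 0.
    Genes absent from a condition's tested set get 0 and are listed in
    ``result.attrs['untested']``.
    """
    if condition_order is None:
        condition_order = list(tables)
    missing = set(condition_order) - set(tables)
    if missing:
        raise ValueError(f"missing condition table(s): {sorted(missing)}")
    genes = sorted(resistant_genes)
    sig = pd.DataFrame(0, index=genes, columns=condition_order, dtype=int)
    untested: list[tuple[str, str]] = []
    for cond in condition_order:
        t = tables[cond]
        maintained, _ = call_resistant(t, fdr_max=fdr_max)
        for g in genes:
            if g not in t.index:
                untested.append((g, cond))
            elif g in maintained:
                sig.loc[g, cond] = 1
    sig.attrs["untested"] = untested
    sig.attrs["condition_order"] = list(condition_order)
    return sig


def signature_type_census(signature: pd.DataFrame
                          ) -> tuple[int, dict[tuple, int]]:
    """Number of distinct signature patterns and genes per pattern."""
    values = signature.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("signature entries must be 0/1")
    patterns = Counter(tuple(int(v) for v in row) for row in values)
    return len(patterns), dict(patterns)


def classify_combo_effect(s_a: int, s_b: int, s_ab: int) -> ComboEffect:
    """Classify the effect of combining treatments A and B on one gene.

    Inputs are resistance-maintained flags (1 = still resistant) under
    single treatments A and B and the combined treatment AB:

    - insensitive: resistant throughout (1,1,1);
    - synergistic: resistance lost only in the combination (1,1,0);
    - adverse: a single treatment removed resistance but the combination
      restored it (s_ab = 1 with s_a = 0 or s_b = 0);
    - neutral: single-treatment loss carried through the combination
      (s_ab = 0 with s_a = 0 or s_b = 0).
    """
    flags = (s_a, s_b, s_ab)
    if any(f not in (0, 1) for f in flags):
        raise ValueError(f"flags must be 0/1, got {flags}")
    if s_ab == 1:
        return ComboEffect.INSENSITIVE if (s_a, s_b) == (1, 1) else ComboEffect.ADVERSE
    return ComboEffect.SYNERGISTIC if (s_a, s_b) == (1, 1) else ComboEffect.NEUTRAL


def classify_combo_table(signature: pd.DataFrame, cond_a: str, cond_b: str,
                         cond_ab: str) -> pd.Series:
    """Per-gene ComboEffect labels for one treatment pair.

    Genes untested in any of the three conditions go into an explicit
    ``unclassified`` bucket rather than being dropped.
    """
    for c in (cond_a, cond_b, cond_ab):
        if c not in signature.columns:
            raise ValueError(f"condition {c!r} absent from signature matrix")
    untested = {g for g, c in signature.attrs.get("untested", [])
                if c in (cond_a, cond_b, cond_ab)}
    labels = {}
    for g in signature.index:
        if g in untested:
            labels[g] = "unclassified"
        else:
            labels[g] = classify_combo_effect(
                int(signature.loc[g, cond_a]),
                int(signature.loc[g, cond_b]),
                int(signature.loc[g, cond_ab])).value
    return pd.Series(labels, name=f"{cond_a}|{cond_b}|{cond_ab}")


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    ``N`` genes in the universe, ``K`` of them marked, ``n`` drawn, ``k``
    of the draw marked.  Computed by summing the exact mass in log space.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent sizes k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    logpmf = (gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
              + gammaln(N - K + 1) - gammaln(n - i + 1)
              - gammaln(N - K - n + i + 1)
              + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1))
    return float(np.exp(logsumexp(logpmf)))


def misregulation_reduction_pct(n_control: int, n_treated: int) -> float:
    """Percent reduction in misregulated-gene count after a treatment,
    100 * (n_control - n_treated) / n_control."""
    if n_control <= 0 or n_treated < 0:
        raise ValueError("counts must be positive control, non-negative treated")
    return 100.0 * (n_control - n_treated) / n_control


def venn_regions(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every non-empty membership region of 2-4 gene sets.

    Keys are tuples of the set names an element belongs to (exactly);
    values sum to the size of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_regions supports 2-4 sets")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names
                                         if n not in combo))
            regions[combo] = len(inside - outside)
    return regions
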