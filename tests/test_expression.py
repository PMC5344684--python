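"""Counting, normalization, filtering, and the exact NB test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from reprosist import expression as expr
from reprosist import synthetic_data as sim


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def brute_force_counts(fragments, annotation):
    """O(reads x exons) oracle: a read hits a gene iff it overlaps any exon."""
    counts = {g: 0 for g in annotation.gene_ids}
    for chrom, start, end in fragments:
        for row in annotation.table.itertuples():
            if row.chrom != chrom:
                continue
            if any(start < e and s < end
                   for s, e in zip(row.exon_starts, row.exon_ends)):
                counts[row.gene_id] += 1
    return pd.Series(counts)


class TestCountGeneReads:
    def test_read_inside_exon_counts_once(self, small_annotation):
        row = small_annotation.table.iloc[0]
        s = row.exon_starts[0]
        counts = expr.count_gene_reads([(row.chrom, s, s + 10)],
                                       small_annotation)
        assert counts[row.gene_id] == 1
        assert counts.sum() == 1

    def test_intronic_read_counts_zero(self, small_annotation):
        row = small_annotation.table.iloc[0]
        intron_start = row.exon_ends[0]
        intron_end = row.exon_starts[1]
        assert intron_end > intron_start, "fixture gene needs an intron"
        counts = expr.count_gene_reads(
            [(row.chrom, intron_start, intron_end)], small_annotation)
        assert counts[row.gene_id] == 0

    def test_invalid_interval_rejected(self, small_annotation):
        chrom = small_annotation.table.iloc[0].chrom
        with pytest.raises(ValueError):
            expr.count_gene_reads([(chrom, 100, 100)], small_annotation)

    def test_matches_brute_force_on_random_fragments(self, small_annotation):
        rng = np.random.default_rng(0)
        (chrom, size), = small_annotation.chrom_sizes.items()
        for _ in range(5):
            starts = rng.integers(0, size - 100, size=200)
            frags = [(chrom, int(s), int(s + rng.integers(1, 500)))
                     for s in starts]
            fast = expr.count_gene_reads(frags, small_annotation)
            slow = brute_force_counts(frags, small_annotation)
            assert (fast.sort_index() == slow.sort_index()).all()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_rpkm_unit_case(self):
        counts = pd.DataFrame({"s": [100, 10 ** 6 - 100]}, index=["g", "h"])
        lengths = pd.Series({"g": 1000, "h": 1000})
        rpkm = expr.rpkm_normalize(counts, lengths)
        assert rpkm.loc["g", "s"] == pytest.approx(100.0)

    def test_cpm_columns_sum_to_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)))
        cpm = expr.cpm_normalize(counts)
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_cpm_scale_invariant(self):
        counts = pd.DataFrame({"a": [10, 20, 30]})
        assert np.allclose(expr.cpm_normalize(counts),
                           expr.cpm_normalize(counts * 2))

    def test_zero_depth_sample_named(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            expr.cpm_normalize(counts)


class TestFilterExpressed:
    def _counts(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=["a1", "a2", "b1", "b2"])

    def test_kept_when_all_of_one_group_passes(self):
        # ~1.2e5 counts of 1e6 depth -> CPM >> 1 in group a, 0 in group b
        counts = self._counts([[120, 150, 0, 0],
                               [10 ** 6, 10 ** 6, 10 ** 6, 10 ** 6]])
        kept = expr.filter_expressed(counts, ["a1", "a2"], ["b1", "b2"])
        assert "g0" in kept

    def test_dropped_when_neither_group_complete(self):
        # gene g0 has CPM < 1 in one sample of each group
        base = 10 ** 6
        counts = self._counts([[0, 5000, 0, 5000], [base, base, base, base]])
        kept = expr.filter_expressed(counts, ["a1", "a2"], ["b1", "b2"])
        assert "g0" not in kept

    def test_all_pass_when_uniformly_expressed(self):
        counts = self._counts([[100, 100, 100, 100]] * 3)
        kept = expr.filter_expressed(counts, ["a1", "a2"], ["b1", "b2"])
        assert len(kept) == 3

    def test_unreplicated_mode_uses_rpkm(self):
        counts = pd.DataFrame({"a": [3000, 997000], "b": [0, 10 ** 6]},
                              index=["g0", "g1"])
        lengths = pd.Series({"g0": 1000, "g1": 1000})
        kept = expr.filter_expressed(counts, ["a"], ["b"],
                                     mode="unreplicated",
                                     transcript_lengths=lengths)
        assert kept == {"g0", "g1"}


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_step_up_worked_example(self):
        # hand enumeration: q(i) = min_{j>=i} m*p(j)/j on sorted p
        q = expr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert expr.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.allclose(expr.bh_fdr([1.0] * 5), 1.0)

    def test_monotone_in_rank_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.random(40)
        q = expr.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(40)
        assert np.allclose(expr.bh_fdr(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expr.bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# exact NB test
# ---------------------------------------------------------------------------

def binomial_conditional_pvalue(y1, s, n1, n2):
    """Enumeration oracle: two-sided conditional binomial tail (phi = 0)."""
    y = np.arange(s + 1)
    logp = (gammaln(s + 1) - gammaln(y + 1) - gammaln(s - y + 1)
            + y * np.log(n1 / (n1 + n2)) + (s - y) * np.log(n2 / (n1 + n2)))
    p = np.exp(logp)
    return min(p[p <= p[y1] * (1 + 1e-9)].sum(), 1.0)


class TestNbExactDe:
    def test_symmetric_counts_give_null_result(self):
        counts = pd.DataFrame({"a1": [50, 10], "a2": [60, 12],
                               "b1": [50, 10], "b2": [60, 12]})
        t = expr.nb_exact_de(counts, ["a1", "a2"], ["b1", "b2"],
                             expr.DEParams(dispersion=0.0))
        assert np.allclose(t["logFC"], 0.0)
        assert np.allclose(t["pvalue"], 1.0)

    def test_phi_zero_equals_binomial_tail(self):
        counts = pd.DataFrame({"a1": [0], "a2": [0],
                               "b1": [100], "b2": [120]})
        # equalize depths by testing a single gene with identical lib sizes
        counts.loc["pad"] = [220, 220, 120, 100]
        t = expr.nb_exact_de(counts, ["a1", "a2"], ["b1", "b2"],
                             expr.DEParams(dispersion=0.0))
        expected = binomial_conditional_pvalue(0, 220, 2, 2)
        assert t["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_group_swap_flips_logfc_keeps_p(self, small_experiment):
        _, counts, meta, _ = small_experiment
        es = list(meta.index[meta["condition"] == "ES-NT"])
        mef = list(meta.index[meta["condition"] == "MEF-NT.WT"])
        fwd = expr.nb_exact_de(counts, es, mef, expr.DEParams(dispersion=0.05))
        rev = expr.nb_exact_de(counts, mef, es, expr.DEParams(dispersion=0.05))
        assert np.allclose(fwd["pvalue"], rev["pvalue"])
        assert np.allclose(fwd["logFC"], -rev["logFC"])

    def test_zero_depth_group_rejected(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [5, 5]})
        with pytest.raises(ValueError):
            expr.nb_exact_de(counts, ["a"], ["b"])

    def test_empirical_fdr_on_planted_mixture(self):
        # 10% planted effects (4x, both directions, as in the NT design
        # where MEF- and ES-resistant genes coexist); BH at 0.05 keeps
        # empirical FDR <= 0.1
        rng = np.random.default_rng(3)
        n, phi, mu = 1500, 0.05, 100
        size = 1 / phi
        mean = np.full((n, 4), float(mu))
        mean[:75, 2:] *= 4.0
        mean[75:150, 2:] /= 4.0
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + mean)),
            columns=["a1", "a2", "b1", "b2"])
        t = expr.nb_exact_de(counts, ["a1", "a2"], ["b1", "b2"])
        called = t.index[t["fdr"] < 0.05]
        false = sum(1 for g in called if g >= 150)
        assert len(called) > 0
        assert false / len(called) <= 0.1


class TestAgainstEdgeR:
    """Independent oracle: edgeR's exact NB test on the same matrix."""

    def test_matches_edger_exact_test(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(5)
        size = 1 / 0.05
        mu = np.full((30, 4), 100.0)
        mu[:5, 2:] *= 3
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + mu)),
            index=[f"g{i}" for i in range(30)],
            columns=["a1", "a2", "b1", "b2"])
        counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = tmp_path / "edger.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            'counts <- read.delim("counts.tsv", row.names=1)\n'
            'y <- DGEList(counts=counts, group=factor(c("a","a","b","b")))\n'
            'y$samples$norm.factors <- 1\n'
            'et <- exactTest(y, dispersion=0.05)\n'
            'write.table(data.frame(gene=rownames(et$table),'
            ' logFC=et$table$logFC, p=et$table$PValue),'
            ' "edger_out.tsv", sep="\\t", row.names=FALSE, quote=FALSE)\n')
        proc = subprocess.run(["Rscript", str(script)], cwd=tmp_path,
                              capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[-200:]}")
        edger = pd.read_csv(tmp_path / "edger_out.tsv", sep="\t",
                            index_col="gene")
        ours = expr.nb_exact_de(counts, ["a1", "a2"], ["b1", "b2"],
                                expr.DEParams(dispersion=0.05))
        # edgeR quantile-adjusts libraries where we rescale; allow the
        # small resulting wobble on the p-value scale
        dlog = np.abs(np.log10(ours["pvalue"] + 1e-30)
                      - np.log10(edger["p"] + 1e-30))
        assert dlog.max() < 0.2
        assert np.abs(ours["logFC"] - edger["logFC"]).max() < 0.05


class TestCallDe:
    def _table(self, logfc, fdr):
        t = pd.DataFrame({"logFC": logfc, "fdr": fdr,
                          "pvalue": fdr, "mean1": 1.0, "mean2": 1.0})
        return t

    def test_fdr_boundary_is_strict(self):
        up, down = expr.call_de(self._table([2.0], [0.05]))
        assert not up and not down

    def test_logfc_boundary_is_strict(self):
        up, down = expr.call_de(self._table([-1.0], [0.01]), abs_logfc_min=1.0)
        assert not up and not down

    def test_signed_assignment(self):
        up, down = expr.call_de(self._table([2.0, -2.0], [0.01, 0.01]))
        assert up == {0} and down == {1}

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            expr.call_de(self._table([1.0], [0.01]), fdr_max=-0.1)


class TestUnreplicatedRule:
    @pytest.mark.parametrize("m1,m2,called", [
        (10.0, 10.0, False),
        (10.0, 45.0, True),    # |log2 4.5| > 1
        (10.0, 20.0, False),   # logFC ~ 1 exactly (strict, modulo pseudocount)
    ])
    def test_fold_change_calls(self, m1, m2, called):
        out = expr.fold_change_de_unreplicated(
            pd.Series([m1]), pd.Series([m2]), pseudocount=0.0)
        assert bool(out["de"].iloc[0]) is called

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError):
            expr.fold_change_de_unreplicated(pd.Series([-1.0]),
                                             pd.Series([1.0]))


class TestMaTable:
    def test_reference_log_transform_and_row_count(self):
        t = pd.DataFrame({"logFC": [1.0, -1.0], "fdr": [0.01, 0.5],
                          "pvalue": [0.001, 0.4]}, index=["g0", "g1"])
        ref = pd.Series({"g0": 0.0, "g1": 1.0})
        ma = expr.ma_table(t, ref)
        assert len(ma) == 2
        assert ma.loc["g0", "x"] == pytest.approx(0.0)
        assert ma.loc["g1", "x"] == pytest.approx(1.0)
        assert bool(ma.loc["g0", "de"]) and not bool(ma.loc["g1", "de"])

    def test_missing_reference_rejected(self):
        t = pd.DataFrame({"logFC": [1.0], "fdr": [0.01]}, index=["g0"])
        with pytest.raises(ValueError):
            expr.ma_table(t, pd.Series(dtype=float))
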