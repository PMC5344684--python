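# Methods

## Scientific setting

When a somatic nucleus (e.g. a mouse embryonic fibroblast, MEF) is
transplanted into a *Xenopus* oocyte, oocyte factors reprogram it toward an
oocyte type of transcription. Some genes, however, resist reactivation:
the oocyte transcribes them from transplanted embryonic stem cell (ESC)
chromatin but not from MEF chromatin. This package implements the
computational side of an assay that (i) identifies such resistant genes
from nascent-RNA sequencing of nuclear-transfer (NT) samples, (ii) asks
which chromatin-modifier treatments (H3K9/H3K27 demethylases, an H2AK119
deubiquitylase, DNA hypomethylation, alone or combined) remove resistance,
and (iii) relates resistance to repressive chromatin marks around
transcription start sites (TSSs).

## Differential expression: exact conditional NB test

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean μ and dispersion φ, Var = μ + φμ². For a two-group comparison on
equalized library sizes, the within-group sums are NB with sizes n₁/φ and
n₂/φ, and conditional on the total *s* the group-1 sum follows a negative
hypergeometric law that does not involve μ:

P(Y₁ = y | S = s) ∝ C(y + n₁r − 1, y) · C(s − y + n₂r − 1, s − y),  r = 1/φ.

At φ = 0 this reduces to Binomial(s, n₁/(n₁+n₂)), the exact conditional
Poisson test. The two-sided p-value sums the probabilities of all
outcomes no more likely than the observed one (minimum-likelihood rule),
computed in log space. This is the same conditional construction as
edgeR's exact test, against which the implementation is cross-checked in
the test suite (max |Δlog₁₀ p| ≈ 0.03 on a shared fixture; the residual
difference comes from library equalization, below).

Numerical/estimation choices:

- **Library equalization.** Counts are rescaled to the geometric-mean
  library size and rounded, rather than quantile-adjusted. Simpler,
  testable, and indistinguishable in practice at the depths involved.
- **Common dispersion.** Estimated by method of moments pooled over genes
  and groups: φ̂ = Σ(s² − x̄) / Σ(x̄² − s²/n)⁺, where s² and x̄ are the
  within-group sample variance and mean. The denominator correction
  removes the E[x̄²] bias. A fixed dispersion can be supplied instead.
- **logFC.** log₂ of depth-adjusted group means with a 0.5 pseudocount per
  group, preventing infinities at zero counts. Tables are oriented
  group2/group1 and the orientation is recorded in `attrs`.
- **FDR.** Benjamini–Hochberg step-up (via statsmodels). "FDR" without a
  named procedure is read as BH, the conventional choice.

**Known limitation — composition bias.** Library-size normalization by
total counts assumes DE is roughly balanced between directions. If a
large one-directional effect block is planted, null genes absorb an
offsetting apparent shift and the empirical FDR degrades (we measure
~0.26 at 10% one-directional 4× effects vs ~0.02 for a balanced mixture).
Robust scale normalization (TMM/median-of-ratios) is deliberately out of
scope; the NT comparisons of interest have effects in both directions
(MEF-resistant and ES-resistant genes), where total-count normalization
is adequate.

## Resistance calls, signatures, combination effects

A gene is **MEF-resistant** iff FDR < 0.05 and log₂FC(MEF/ES) < 0 in the
after-NT comparison (strict thresholds); ES-resistant symmetrically with
logFC > 0. The **digital signature** repeats this call in every panel
condition against the fixed untreated ES-NT reference: 1 = still
differentially expressed (resistance maintained), 0 = not (resistance
lost). Genes untested in a condition (filtered out) receive 0 with an
explicit flag; treatment-pair classification sends such genes to an
`unclassified` bucket instead of dropping them.

Combination effects for single treatments A, B and their combination AB
use only the three maintained-flags (1 = resistant): (1,1,1) insensitive;
(1,1,0) synergistic; s_AB = 1 with a single-treatment loss → adverse;
s_AB = 0 with a single-treatment loss → neutral. The eight possible
triples partition 1/1/3/3 across the four classes.

Overlap enrichment between gene sets uses the exact hypergeometric upper
tail P(X ≥ k), summed in log space (gammaln + logsumexp) so that values
far below 1e-10 are representable; the universe defaults to the genes
passing the expression filter in the comparison at hand.

## Chromatin profiles

TSS metaplots count read 5′ positions (no fragment extension) in 200 bp
bins over [TSS − 5 kb, TSS + 5 kb), half-open; minus-strand gene vectors
are reversed so bins run 5′→3′ (strand orientation is the default and can
be disabled). Set profiles are bin sums divided by set size and by total
mapped reads in millions; the paired input profile is subtracted
element-wise and may go negative. Reads exactly on a bin edge belong to
the downstream bin by the half-open convention; the mirror-symmetry
property therefore holds exactly only off bin edges.

Promoter methylation is the percentage of CpGs with fraction > 0.95
(strict) among CpGs pooled over strand-aware 3 kb upstream windows
[TSS − 3000, TSS) of the gene set; a per-gene-averaged variant is
exposed as an option.

The gene-set permutation test compares the subset score sum (or mean)
with B same-size uniform draws without replacement from the universe;
the default two-sided p is the fraction of background draws at least as
far from the background mean as the observed value, so p has granularity
1/B. One-sided alternatives are available.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical design* of the assay: an
untreated ES-NT reference plus MEF-NT samples for the 12-condition panel
({WT, Dnmt1N} donors × {none, Kdm4d, Kdm6b, USP21, USP21+Kdm6b,
USP21+Kdm6b+Kdm4d}), two replicates each. Key defaults: 2,000 genes,
100 resistant, per-gene baselines lognormal around 100 expected counts
(sd 0.5 on the log scale), NB dispersion 0.05, planted resistant effect
log₂FC = −2 (MEF below ES), sensitivity signatures drawn per resistant
gene as independent Bernoulli(0.5) inclusion of each of {Kdm4d, Kdm6b,
USP21, Dnmt1N}, a combination rescuing iff any component rescues, and a
sensitive treatment restoring the full deficit (rescue fraction 1.0,
configurable down to partial rescue). ChIP simulation mixes a uniform
floor with excess IP density within ±1 kb of marked TSSs over a uniform
input; methylation draws Beta-distributed CpG fractions with high/low
modes; dual-species alignments assign each read a true species, a contig
and a MAPQ, with a configurable fraction forced to MAPQ ≤ 13.

Not emulated: nucleotide sequences and base qualities, positional biases
within transcripts, batch effects, between-replicate library-size drift
(exposed as parameters but off by default), correlated gene modules, and
the dependence of a real aligner's MAPQ on actual cross-genome homology.
Passing recovery tests therefore demonstrates correctness of the
pipeline's inference under its own model assumptions, not robustness to
every artefact of real NT RNA-seq.

## Heatmap transforms

The before/after heatmap normalization divides each gene's before-NT
samples by its before-NT mean and after-NT samples by its after-NT mean,
takes log₂ with a pseudocount of 2⁻¹⁰ × max(matrix) (configurable), and
z-scores each sample column over the selected genes. Row grouping uses
k-means (k-means++ init, ≤ 300 Lloyd iterations, fixed seed, k = 10
default); row ordering for the clustered heatmaps uses Euclidean
complete-linkage hierarchical clustering with plain dendrogram leaf
order (no optimal-leaf reordering), matching the defaults of the common
R heatmap tooling.

## Imaging

Each nucleus is an ellipsoid: v = 4/3·π·a·b·(thickness/2) with radii a, b
from the largest optical section and thickness from the z-range. Total
fluorescence = mean intensity × v. Normalization is replicate-wise: the
control-group mean maps to 1 arbitrary unit and the injected mean to its
ratio, *before* pooling across replicates for the Mann–Whitney
comparison; a pooled-then-normalized mode is intentionally not offered.

## Problem sizes and determinism

The full synthetic workflow (2,000 genes × 13 comparisons) runs in a few
seconds on one core; permutation tests default to B = 10,000. Every
stochastic component is a pure function of (configuration, seed); the
acceptance script threads a single seed through all of them.
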