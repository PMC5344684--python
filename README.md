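# reprosist

Analysis pipeline for **gene resistance to transcriptional reprogramming
after nuclear transfer**.

When a somatic nucleus (a mouse embryonic fibroblast, MEF) is transplanted
into a *Xenopus* oocyte, oocyte factors reprogram its transcription — but a
subset of genes resists reactivation. Comparing nascent-RNA sequencing of
oocytes carrying MEF vs embryonic stem cell (ESC) nuclei identifies those
resistant genes; repeating the comparison after overexpressing chromatin
modifiers (Kdm4d, Kdm6b, USP21, alone or combined, on normal or
DNA-hypomethylated donor chromatin) reveals which repressive pathways
enforce resistance at each gene. This package implements that pipeline for
computational biologists: from read partitioning and counting through
differential expression, resistance signatures, combination-effect
classification, TSS chromatin metaplots, and image-based fluorescence
quantitation — plus a synthetic-data module that generates every input with
planted ground truth.

## The statistics at the core

- A gene is **resistant** iff, in the after-NT MEF vs ES comparison,
  FDR < 0.05 and log₂FC(MEF/ES) < 0 — the oocyte under-transcribes it from
  MEF chromatin.
- Differential expression uses an **exact conditional negative-binomial
  test**: with per-sample dispersion φ (Var = μ + φμ²) and equalized
  library sizes, the group-1 count sum conditional on the two-group total
  is negative hypergeometric, free of the unknown mean; at φ = 0 it is the
  exact conditional binomial. p-values are two-sided by the
  minimum-likelihood rule; FDR is Benjamini–Hochberg.
- The **digital signature** of a resistant gene is the binary vector over
  the 12-condition panel: 1 where resistance is maintained, 0 where a
  treatment removed it. Comparing single treatments (s_A, s_B) with their
  combination (s_AB) classifies the pair's effect: insensitive (1,1,1),
  synergistic (1,1,0), adverse (s_AB = 1 despite a single-treatment loss),
  neutral (s_AB = 0 with a single-treatment loss).
- Gene-set overlaps use the **exact hypergeometric upper tail** P(X ≥ k);
  chromatin state around TSSs is summarized as input-subtracted, per-gene
  and per-million normalized 200 bp bin profiles over ±5 kb, tested with
  same-size random-set **permutation nulls** and rank-based tests.

## Worked example

Simulate the full 12-condition panel (2,000 genes, 100 planted resistant
genes at log₂FC −2, NB dispersion 0.05, two replicates per condition), run
every condition against the untreated ES-NT reference, and score recovery
against the planted truth:

```python
from reprosist import synthetic_data as sim
from reprosist.workflow import run_synthetic_workflow
from reprosist import resistance as res

cfg = sim.SimConfig(n_genes=2000, n_resistant=100, seed=1)
result = run_synthetic_workflow(cfg)
print("called MEF-resistant:", len(result.mef_resistant))
print("sensitivity:", result.sensitivity,
      "empirical FDR:", round(result.empirical_fdr, 4))
print("signature bits correct:", round(result.signature_bit_accuracy, 4))
n_types, _ = res.signature_type_census(result.signature)
print("signature types:", n_types, "genes:", len(result.signature))
```

prints

```
called MEF-resistant: 96
sensitivity: 0.95 empirical FDR: 0.0104
signature bits correct: 0.9807
signature types: 24 genes: 96
```

95 of the 100 planted resistant genes are recalled with one false positive
among 96 calls, and 98% of the 12-condition signature bits match the
planted sensitivity patterns. An overlap-enrichment call looks like:

```python
>>> res.hypergeometric_overlap(22, 79, 165, 13827)
1.276e-24   # P(X >= 22) for a 22/79 overlap with 165 marked of 13,827
```

A thin CLI mirrors the library (`reprosist simulate`, `partition`, `de`,
`signature`, `combo`, `overlap`, `cluster`, `permtest`, `imaging`); run
`reprosist --help`.

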