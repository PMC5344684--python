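"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of the NT reprogramming study design:
BrUTP-labelled nascent RNA-seq counts for ES-NT and MEF-NT samples across a
panel of chromatin-modifier conditions, ChIP IP/input read positions around
TSSs, promoter CpG methylation fractions, alignments against a concatenated
two-species genome, and two-group nucleus-measurement tables.  Every
generator is a pure function of its configuration and seed, and returns the
planted truth alongside the data so downstream stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from reprosist.annotation import GeneAnnotation
from reprosist.conditions import Condition, default_panel

#: single treatments a resistant gene's sensitivity signature may contain.
#: ``Dnmt1N`` acts through the donor genotype; the rest through oocyte
#: overexpression.
SINGLE_TREATMENTS = ("Kdm4d", "Kdm6b", "USP21", "Dnmt1N")


@dataclass
class SimConfig:
    """Configuration of the count-matrix simulation.

    Defaults mirror the study design: a 12-condition panel ({WT, Dnmt1N}
    donor genotypes x 6 modifier sets) with two biological replicates per
    condition; negative-binomial noise Var = mu + phi*mu^2; resistant genes
    planted at log2(MEF/ES) = ``resistant_logfc`` in the untreated
    condition, with a sensitive treatment restoring ``rescue_logfc_fraction``
    of the deficit.
    """

    n_genes: int = 2000
    n_resistant: int = 100
    treatments: list[Condition] = field(default_factory=default_panel)
    replicates_per_condition: int = 2
    base_mean: float = 100.0
    dispersion: float = 0.05
    resistant_logfc: float = -2.0
    rescue_logfc_fraction: float = 1.0
    library_size: int | None = None  # None -> n_genes * base_mean
    sensitivity_prob: float = 0.5
    gene_mean_sd: float = 0.5  # lognormal sd of per-gene baseline means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_resistant <= self.n_genes:
            raise ValueError("need 0 <= n_resistant <= n_genes")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be positive")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.rescue_logfc_fraction <= 1:
            raise ValueError("rescue_logfc_fraction must be in [0, 1]")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size must be positive")


@dataclass
class SimTruth:
    """Planted ground truth recorded by the generators."""

    resistant_genes: set[str] = field(default_factory=set)
    #: gene id -> subset of SINGLE_TREATMENTS that removes its resistance
    sensitivity_signature: dict[str, frozenset[str]] = field(default_factory=dict)
    species_of_read: dict[str, str] = field(default_factory=dict)
    marked_genes: set[str] = field(default_factory=set)
    hypermethylated_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not set(self.sensitivity_signature) <= self.resistant_genes:
            raise ValueError("signature keys must be resistant genes")


def effective_treatments(condition: Condition) -> frozenset[str]:
    """Single treatments acting in a condition: its overexpressed modifiers
    plus ``Dnmt1N`` when the donor genotype is DNA-hypomethylated."""
    t = set(condition.modifiers) & set(SINGLE_TREATMENTS)
    if condition.genotype == "Dnmt1N":
        t.add("Dnmt1N")
    return frozenset(t)


def condition_rescues(condition: Condition, sensitivity: frozenset[str],
                      rule: str = "any") -> bool:
    """Whether a condition removes resistance for a gene with the given
    single-treatment sensitivity set.

    ``rule='any'`` (default): the combined treatment rescues iff any of its
    components rescues.  ``rule='all'``: every component must rescue.
    """
    acting = effective_treatments(condition)
    if not acting:
        return False
    if rule == "any":
        return bool(acting & sensitivity)
    if rule == "all":
        return acting <= sensitivity
    raise ValueError(f"unknown interaction rule {rule!r}")


def expected_signature(truth: SimTruth, conditions: list[Condition],
                       rule: str = "any") -> pd.DataFrame:
    """Truth-derived digital signature: 1 where a planted resistant gene
    keeps its resistance under a condition, 0 where the condition rescues."""
    genes = sorted(truth.resistant_genes)
    data = {
        c.label: [
            0 if condition_rescues(c, truth.sensitivity_signature[g], rule) else 1
            for g in genes
        ]
        for c in conditions
    }
    return pd.DataFrame(data, index=genes)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def make_annotation(config: SimConfig, chrom: str = "chrT",
                    gene_spacing: int = 15_000,
                    n_exons: int = 3) -> GeneAnnotation:
    """Toy single-chromosome annotation with genes spaced so that +/-5 kb
    TSS windows (and 3 kb promoters) stay on the chromosome.

    Genes alternate strand; each carries ``n_exons`` exons laid out
    deterministically from the seed.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(config.seed)
    margin = 6_000  # keeps the +/-5 kb window of every TSS on-chromosome
    rows = []
    for i in range(config.n_genes):
        start = margin + i * gene_spacing
        body = int(rng.integers(2_000, 8_000))
        end = start + body
        strand = "+" if i % 2 == 0 else "-"
        # split the body into n_exons exons separated by introns
        cuts = np.sort(rng.choice(np.arange(1, body), size=2 * n_exons - 1,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [body]])
        exon_starts = [start + int(bounds[2 * j]) for j in range(n_exons)]
        exon_ends = [start + int(bounds[2 * j + 1]) for j in range(n_exons)]
        tx_length = sum(e - s for s, e in zip(exon_starts, exon_ends))
        rows.append(dict(gene_id=f"g{i:05d}", chrom=chrom, start=start,
                         end=end, strand=strand, exon_starts=exon_starts,
                         exon_ends=exon_ends, tx_length=tx_length))
    size = margin + config.n_genes * gene_spacing + margin
    return GeneAnnotation(pd.DataFrame(rows), {chrom: size})


# ---------------------------------------------------------------------------
# NT count matrices
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draw with Var = mu + phi*mu^2 (Poisson at phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_nt_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the NT nascent-RNA count matrix for the treatment panel.

    Samples are an untreated ES-NT reference plus MEF-NT samples for every
    condition in ``config.treatments``, ``replicates_per_condition`` each.
    Non-resistant genes share their mean across donors; a resistant gene's
    MEF mean is ES mean x 2**resistant_logfc in the untreated condition, and
    a sensitive treatment restores ``rescue_logfc_fraction`` of that deficit
    (1.0 = full restoration).

    Returns ``(counts, metadata, truth)``: a genes x samples integer
    DataFrame, a per-sample metadata DataFrame (columns ``donor``,
    ``condition``, ``genotype``, ``replicate``, ``stage``), and the planted
    truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    # per-gene baseline means, lognormal around base_mean
    base = config.base_mean * rng.lognormal(
        -0.5 * config.gene_mean_sd ** 2, config.gene_mean_sd, size=n)
    lib = config.library_size or int(config.n_genes * config.base_mean)
    base *= lib / base.sum()

    resistant_idx = rng.choice(n, size=config.n_resistant, replace=False)
    resistant = {genes[i] for i in resistant_idx}
    signature: dict[str, frozenset[str]] = {}
    for g in sorted(resistant):
        picks = rng.random(len(SINGLE_TREATMENTS)) < config.sensitivity_prob
        signature[g] = frozenset(
            t for t, hit in zip(SINGLE_TREATMENTS, picks) if hit)
    truth = SimTruth(resistant_genes=resistant, sensitivity_signature=signature)

    res_mask = np.zeros(n, dtype=bool)
    res_mask[resistant_idx] = True
    deficit = 2.0 ** config.resistant_logfc  # < 1 for negative planted logFC

    columns: dict[str, np.ndarray] = {}
    meta_rows = []

    def add_samples(label: str, donor: str, genotype: str,
                    mean: np.ndarray) -> None:
        for r in range(1, config.replicates_per_condition + 1):
            sid = f"{label}.rep{r}"
            columns[sid] = _nb_sample(rng, mean, config.dispersion)
            meta_rows.append(dict(sample_id=sid, donor=donor,
                                  condition=label, genotype=genotype,
                                  replicate=r, stage="after-NT"))

    add_samples("ES-NT", "ES", "WT", base)

    for cond in config.treatments:
        mean = base.copy()
        rescued = np.array([
            res_mask[i]
            and condition_rescues(cond, signature[genes[i]])
            for i in range(n)
        ])
        full_res = res_mask & ~rescued
        mean[full_res] *= deficit
        # partial restoration: residual logFC = resistant_logfc * (1 - f)
        residual = 2.0 ** (config.resistant_logfc
                           * (1.0 - config.rescue_logfc_fraction))
        mean[res_mask & rescued] *= residual
        add_samples(f"MEF-NT.{cond.label}", "MEF", cond.genotype, mean)

    counts = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta, truth


# ---------------------------------------------------------------------------
# ChIP reads
# ---------------------------------------------------------------------------

@dataclass
class ChipParams:
    """IP/input read simulation: ``n_ip``/``n_input`` total reads;
    ``enrichment`` is the fraction of IP reads drawn from TSS peaks of
    marked genes (uniform within ``+/- peak_halfwidth`` of the TSS); the
    rest fall uniformly on the chromosome."""

    n_ip: int = 100_000
    n_input: int = 100_000
    enrichment: float = 0.5
    peak_halfwidth: int = 1_000

    def __post_init__(self) -> None:
        if self.n_ip < 0 or self.n_input < 0:
            raise ValueError("read counts must be non-negative")
        if not 0 <= self.enrichment <= 1:
            raise ValueError("enrichment must be in [0, 1]")


def simulate_chip_reads(
    annotation: GeneAnnotation, marked: set[str], params: ChipParams,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate IP and input read 5'-positions on the toy chromosome.

    Returns two DataFrames with columns ``chrom`` and ``pos``.  Input reads
    are uniform; IP reads mix a uniform floor with excess density within
    ``+/- peak_halfwidth`` of the TSSs of ``marked`` genes.
    """
    unknown = set(marked) - set(annotation.gene_ids)
    if unknown:
        raise ValueError(f"marked genes not in annotation: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    (chrom, size), = annotation.chrom_sizes.items()

    def uniform(n: int) -> np.ndarray:
        return rng.integers(0, size, size=n)

    if params.n_ip == 0:
        ip_pos = np.array([], dtype=int)
    elif marked and params.enrichment > 0:
        n_peak = rng.binomial(params.n_ip, params.enrichment)
        tss = annotation.tss().loc[sorted(marked)].to_numpy()
        centers = tss[rng.integers(0, len(tss), size=n_peak)]
        offsets = rng.integers(-params.peak_halfwidth, params.peak_halfwidth,
                               size=n_peak)
        peak_pos = np.clip(centers + offsets, 0, size - 1)
        ip_pos = np.concatenate([peak_pos, uniform(params.n_ip - n_peak)])
    else:
        ip_pos = uniform(params.n_ip)

    input_pos = uniform(params.n_input)
    ip = pd.DataFrame({"chrom": chrom, "pos": ip_pos})
    inp = pd.DataFrame({"chrom": chrom, "pos": input_pos})
    return ip, inp


# ---------------------------------------------------------------------------
# promoter methylation
# ---------------------------------------------------------------------------

@dataclass
class MethParams:
    """CpG simulation: ``cpgs_per_promoter`` CpGs placed uniformly in the
    3 kb strand-aware upstream window; fractions drawn Beta(a, b) with a
    high mode for hypermethylated genes and a low mode otherwise."""

    cpgs_per_promoter: int = 20
    upstream: int = 3_000
    high_mode: tuple[float, float] = (20.0, 1.0)
    low_mode: tuple[float, float] = (1.0, 20.0)

    def __post_init__(self) -> None:
        if self.cpgs_per_promoter < 0:
            raise ValueError("CpG density must be non-negative")


def simulate_methylation(annotation: GeneAnnotation, hyper: set[str],
                         params: MethParams, seed: int) -> pd.DataFrame:
    """Per-CpG methylation table (``chrom``, ``pos``, ``fraction``)."""
    unknown = set(hyper) - set(annotation.gene_ids)
    if unknown:
        raise ValueError(f"hyper genes not in annotation: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    tss = annotation.tss()
    strands = annotation.table.set_index("gene_id")["strand"]
    rows = []
    for g in annotation.gene_ids:
        t = int(tss.loc[g])
        if strands.loc[g] == "+":
            lo, hi = t - params.upstream, t
        else:
            lo, hi = t + 1, t + 1 + params.upstream
        lo = max(lo, 0)
        pos = np.sort(rng.choice(np.arange(lo, hi),
                                 size=min(params.cpgs_per_promoter, hi - lo),
                                 replace=False))
        a, b = params.high_mode if g in hyper else params.low_mode
        frac = rng.beta(a, b, size=len(pos))
        chrom = annotation.table.set_index("gene_id").loc[g, "chrom"]
        for p, f in zip(pos, frac):
            rows.append((chrom, int(p), float(f)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "fraction"])
    return df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dual-species alignments
# ---------------------------------------------------------------------------

@dataclass
class DualSpeciesParams:
    """Alignment simulation against a concatenated two-species genome.

    ``contigs`` maps each of exactly two species labels to its contig
    names; ``ambiguity_fraction`` of reads receive MAPQ <= ``mapq_max_low``
    to emulate cross-genome multi-mappers; ``unmapped_fraction`` receive no
    alignment at all."""

    n_reads: int = 10_000
    contigs: dict[str, list[str]] = field(default_factory=lambda: {
        "mouse": ["chr1_mm", "chr2_mm"],
        "xenopus": ["scaffold1_xl", "scaffold2_xl"],
    })
    ambiguity_fraction: float = 0.0
    unmapped_fraction: float = 0.0
    contig_length: int = 1_000_000
    mapq_max_low: int = 13
    mapq_high: tuple[int, int] = (20, 60)

    def __post_init__(self) -> None:
        if len(self.contigs) != 2:
            raise ValueError("exactly two species required")
        names = [c for v in self.contigs.values() for c in v]
        if len(names) != len(set(names)):
            raise ValueError("contig names overlap between species")
        if not 0 <= self.ambiguity_fraction <= 1:
            raise ValueError("ambiguity_fraction must be in [0, 1]")
        if not 0 <= self.unmapped_fraction <= 1:
            raise ValueError("unmapped_fraction must be in [0, 1]")


def simulate_dual_species_alignments(
    params: DualSpeciesParams, seed: int,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate alignment records (``read_id``, ``contig`` or None,
    ``pos``, ``mapq``, ``mapped``) plus the per-read true species."""
    rng = np.random.default_rng(seed)
    species = sorted(params.contigs)
    rows = []
    truth = SimTruth()
    for i in range(params.n_reads):
        rid = f"r{i:07d}"
        sp = species[int(rng.integers(0, 2))]
        truth.species_of_read[rid] = sp
        if rng.random() < params.unmapped_fraction:
            rows.append(dict(read_id=rid, contig=None, pos=-1, mapq=0,
                             mapped=False))
            continue
        contig = params.contigs[sp][int(rng.integers(0, len(params.contigs[sp])))]
        if rng.random() < params.ambiguity_fraction:
            mapq = int(rng.integers(0, params.mapq_max_low + 1))
        else:
            mapq = int(rng.integers(params.mapq_high[0],
                                    params.mapq_high[1] + 1))
        pos = int(rng.integers(0, params.contig_length))
        rows.append(dict(read_id=rid, contig=contig, pos=pos, mapq=mapq,
                         mapped=True))
    cols = ["read_id", "contig", "pos", "mapq", "mapped"]
    return pd.DataFrame(rows, columns=cols), truth


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

@dataclass
class NucleiParams:
    """Two-group nucleus simulation: ``ratio`` is the injected/control mean
    fluorescence ratio, ``noise`` the lognormal sd of per-nucleus
    fluorescence, dims in micrometres."""

    n_per_group: int = 20
    n_replicates: int = 3
    ratio: float = 0.5
    noise: float = 0.1
    radius_mean: float = 5.0
    thickness_mean: float = 6.0
    dim_noise: float = 0.1
    base_fluorescence: float = 100.0

    def __post_init__(self) -> None:
        if min(self.radius_mean, self.thickness_mean,
               self.base_fluorescence) <= 0:
            raise ValueError("dimensions and fluorescence must be positive")
        if self.ratio < 0 or self.noise < 0:
            raise ValueError("ratio and noise must be non-negative")


def simulate_nuclei(params: NucleiParams, seed: int) -> pd.DataFrame:
    """Nucleus measurement table: columns ``radius_a``, ``radius_b``,
    ``thickness``, ``mean_fluorescence``, ``group``, ``replicate``."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, params.n_replicates + 1):
        for group, scale in (("control", 1.0), ("injected", params.ratio)):
            for _ in range(params.n_per_group):
                dims = [
                    d * (rng.lognormal(0.0, params.dim_noise)
                         if params.dim_noise > 0 else 1.0)
                    for d in (params.radius_mean, params.radius_mean,
                              params.thickness_mean)
                ]
                fl = params.base_fluorescence * scale
                if params.noise > 0:
                    fl *= rng.lognormal(-0.5 * params.noise ** 2, params.noise)
                rows.append(dict(radius_a=dims[0], radius_b=dims[1],
                                 thickness=dims[2], mean_fluorescence=fl,
                                 group=group, replicate=rep))
    cols = ["radius_a", "radius_b", "thickness", "mean_fluorescence",
            "group", "replicate"]
    return pd.DataFrame(rows, columns=cols)
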