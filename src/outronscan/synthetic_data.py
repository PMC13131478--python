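"""Synthetic genomes, coverage tracks, count matrices and small-RNA records.

The generator emulates the statistical structure of a strand-specific total
RNA-seq experiment in a nematode under knockdown of the Integrator catalytic
subunit:

* a toy chromosome of isolated protein-coding genes, a fraction of which gain
  outron signal (un-trans-spliced 5' region) in the treatment condition;
* an snRNA cluster whose loci acquire exponentially decaying transcription-
  termination readthrough of known extent in the treatment, with
  "operon-like" downstream genes placed inside the readthrough windows;
* enhancer/regulatory elements with controlled fold changes;
* negative-binomial count matrices for a 2-genotype x 2-treatment design with
  planted reversed / attenuated / null genes;
* small-RNA read records with planted 22G-target quadrant structure.

Every output is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coverage_engine import CoverageTrack
from .genome_model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    RegulatoryElement,
    TranscriptModel,
)

CHROM = "chrS"

_COND_CODE = {"control": 1, "treatment": 2}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0

    # genome layout
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (1000, 3000)
    intergenic_gap_range: tuple[int, int] = (1500, 3000)

    # coverage model
    lambda_body: float = 5.0
    background_lambda: float = 0.01
    outron_background_fraction: float = 0.1  # f0: outron lambda = f0 * lambda_body
    retained_fraction: float = 0.25
    outron_shift: float = 1.0  # log2 usage shift for retained genes in treatment
    n_replicates: int = 3
    read_length: int = 40

    # snRNA readthrough
    n_snrna: int = 3
    readthrough_extents: tuple[int, ...] = (1000, 5000, 15000)
    decay_tau: float = 2000.0
    readthrough_floor: float = 0.2  # decay floor as a fraction of lambda_body
    snrna_length: int = 150
    downstream_gene_fraction: float = 0.05  # basal expression of corridor genes

    # promoter-upstream antisense (PROMPT-like) signal
    n_antisense: int = 10
    antisense_lfc: float = 2.0
    antisense_base_fraction: float = 0.05
    antisense_window: int = 400

    # regulatory elements
    n_enhancers: int = 20
    enhancer_lfc: float = 1.5
    enhancer_base_fraction: float = 0.3

    # NB count matrices (genotype x treatment design)
    n_count_genes: int = 1000
    counts_mean: float = 100.0
    dispersion: float = 0.05
    n_reps_counts: int = 3
    beta_treatment: float = -2.5  # log2, wild-type knockdown effect for planted genes
    beta_interaction_reversed: float = 3.0  # log2; combined mutant effect = +0.5
    beta_interaction_attenuated: float = 2.0  # log2; combined mutant effect = -0.5
    n_reversed: int = 100
    n_attenuated: int = 100
    n_null: int = 800
    depth_sd: float = 0.15  # lognormal sd of per-sample depth factors

    # small-RNA module
    n_smallrna_genes: int = 1000
    n_targets: int = 50
    smallrna_mean: float = 50.0
    smallrna_dispersion: float = 0.1
    target_22g_lfc: float = 3.0  # log2
    target_mrna_lfc: float = -2.0  # log2
    g_bias: float = 0.75
    n_reads: int = 2000
    n_mirna: int = 10

    def __post_init__(self) -> None:
        for name in ("outron_background_fraction", "retained_fraction", "g_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_reversed + self.n_attenuated + self.n_null != self.n_count_genes:
            raise ConfigError("planted class counts must sum to n_count_genes")
        if self.intergenic_gap_range[0] < 500:
            raise ConfigError("intergenic gaps must be >= 500 bp to keep genes eligible")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    retained: dict[str, bool] = field(default_factory=dict)
    usage_shift: dict[str, float] = field(default_factory=dict)
    snrna_extent: dict[str, int] = field(default_factory=dict)
    readthrough_window_genes: dict[str, list[str]] = field(default_factory=dict)
    enhancer_upregulated: dict[str, bool] = field(default_factory=dict)
    antisense_upregulated: dict[str, bool] = field(default_factory=dict)
    count_class: dict[str, str] = field(default_factory=dict)  # reversed/attenuated/null
    count_betas: dict[str, tuple[float, float]] = field(default_factory=dict)  # (b_t, b_i) log2
    target_22g: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, flag in self.retained.items():
            rows.append(("outron", gid, "retained", flag))
        for gid, ext in self.snrna_extent.items():
            rows.append(("readthrough", gid, "extent", ext))
        for gid, cls in self.count_class.items():
            rows.append(("counts", gid, "class", cls))
        for gid, flag in self.target_22g.items():
            rows.append(("smallrna", gid, "target", flag))
        return pd.DataFrame(rows, columns=["module", "id", "key", "value"])


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def build_genome(config: SimulationConfig) -> tuple[AnnotationSet, GroundTruth]:
    """Lay out the toy chromosome and record ground truth.

    Main protein-coding genes are isolated (eligible under the default outron
    filters); each snRNA locus is followed by a readthrough corridor holding
    a sense-strand and an antisense-strand downstream gene.
    """
    rng = _rng(config, 11)
    truth = GroundTruth()
    genes: list[GeneModel] = []
    regulatory: list[RegulatoryElement] = []

    lo_len, hi_len = config.gene_length_range
    lo_gap, hi_gap = config.intergenic_gap_range
    cursor = 2000

    n_retained = int(round(config.retained_fraction * config.n_genes))
    retained_idx = set(
        rng.choice(config.n_genes, size=n_retained, replace=False).tolist()
    )
    antisense_idx = set(
        rng.choice(
            config.n_genes,
            size=min(config.n_antisense, config.n_genes),
            replace=False,
        ).tolist()
    )

    def make_gene(gene_id: str, start: int, length: int, strand: str, biotype: str) -> GeneModel:
        span = GenomicInterval(CHROM, start, start + length, strand)
        tx_main = TranscriptModel(gene_id + ".1", gene_id, strand, (span,))
        txs = [tx_main]
        if length >= 900 and biotype == "protein_coding":
            short = GenomicInterval(CHROM, start, start + int(length * 0.6), strand)
            txs.append(TranscriptModel(gene_id + ".2", gene_id, strand, (short,)))
        return GeneModel(gene_id, biotype, strand, span, tuple(txs), tx_main)

    for i in range(config.n_genes):
        cursor += int(rng.integers(lo_gap, hi_gap + 1))
        length = int(rng.integers(max(lo_len, 500), hi_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i:04d}"
        gene = make_gene(gid, cursor, length, strand, "protein_coding")
        genes.append(gene)
        truth.retained[gid] = i in retained_idx
        truth.usage_shift[gid] = config.outron_shift if i in retained_idx else 0.0
        truth.antisense_upregulated[gid] = i in antisense_idx
        # coding promoter element upstream of the TSS
        p_lo = gene.tss - 200 if strand == "+" else gene.tss
        p_hi = gene.tss if strand == "+" else gene.tss + 200
        if p_lo >= 0:
            regulatory.append(
                RegulatoryElement(
                    GenomicInterval(CHROM, p_lo, p_hi, strand),
                    "coding_promoter",
                    f"prom{i:04d}",
                    gid,
                )
            )
        cursor += length

    # snRNA cluster with planned readthrough corridors (all plus strand so the
    # corridor extends rightwards)
    extents = list(config.readthrough_extents)
    cursor += 5000
    snrna_region_start = cursor
    for j in range(config.n_snrna):
        extent = int(extents[j % len(extents)])
        sid = f"snrna{j:02d}"
        sn = make_gene(sid, cursor, config.snrna_length, "+", "snRNA")
        genes.append(sn)
        truth.snrna_extent[sid] = extent
        regulatory.append(
            RegulatoryElement(
                GenomicInterval(CHROM, cursor, cursor + config.snrna_length, "+"),
                "ncRNA",
                f"nc{j:02d}",
                sid,
            )
        )
        window_genes: list[str] = []
        if extent >= 2000:
            # sense-strand downstream gene inside the readthrough window
            g_start = sn.tes + max(500, extent // 3)
            g_len = min(1000, extent // 3)
            did = f"ds_{sid}_s"
            genes.append(make_gene(did, g_start, g_len, "+", "protein_coding"))
            window_genes.append(did)
            # antisense gene, also inside the window
            a_start = sn.tes + extent // 2
            a_len = min(800, extent // 4)
            aid = f"ds_{sid}_a"
            genes.append(make_gene(aid, a_start, a_len, "-", "protein_coding"))
            window_genes.append(aid)
        truth.readthrough_window_genes[sid] = window_genes
        cursor = sn.tes + extent + 2000

    # enhancers: half intragenic, half intergenic; a random half upregulated.
    # Intergenic enhancers stay clear of the readthrough corridors so corridor
    # signal is attributable to the snRNA loci alone.
    main_spans = [g.span for g in genes if g.gene_id.startswith("gene")]
    for k in range(config.n_enhancers):
        eid = f"enh{k:03d}"
        up = bool(rng.random() < 0.5)
        if k % 2 == 0 and main_spans:
            host = main_spans[int(rng.integers(len(main_spans)))]
            if len(host) > 600:
                start = host.start + int(rng.integers(100, len(host) - 500))
            else:
                start = host.start + 50
        else:
            start = int(rng.integers(2000, max(snrna_region_start - 500, 2500)))
        iv = GenomicInterval(CHROM, start, start + 300, ".")
        regulatory.append(RegulatoryElement(iv, "putative_enhancer", eid))
        truth.enhancer_upregulated[eid] = up

    chrom_size = cursor + 20000
    annotation = AnnotationSet(genes, regulatory, {CHROM: chrom_size})
    return annotation, truth


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def _outron_interval(gene: GeneModel, window: int = 150) -> GenomicInterval | None:
    if gene.strand == "+":
        lo, hi = gene.tss - window, gene.tss
    else:
        lo, hi = gene.tss, gene.tss + window
    lo = max(lo, 0)
    if hi <= lo:
        return None
    return GenomicInterval(gene.chrom, lo, hi, gene.strand)


def simulate_tracks(
    annotation: AnnotationSet,
    truth: GroundTruth,
    config: SimulationConfig,
    condition: str,
    replicate: int = 0,
) -> dict[str, CoverageTrack]:
    """Poisson per-base coverage for one condition/replicate, both strands."""
    if condition not in _COND_CODE:
        raise ValueError(f"condition must be control or treatment, got {condition!r}")
    rng = _rng(config, 23, _COND_CODE[condition], replicate)
    size = annotation.chrom_sizes[CHROM]
    lam = {
        "+": np.full(size, config.background_lambda),
        "-": np.full(size, config.background_lambda),
    }
    treated = condition == "treatment"
    corridor_gene_ids = {
        gid for gids in truth.readthrough_window_genes.values() for gid in gids
    }

    for gene in annotation:
        strand = gene.strand
        body_lambda = config.lambda_body
        if gene.gene_id in corridor_gene_ids:
            # corridor genes are basally quiet so that coverage gains there
            # reflect invading readthrough, as in the interference model
            body_lambda = config.downstream_gene_fraction * config.lambda_body
        lam[strand][gene.span.start : gene.span.end] = body_lambda
        if gene.biotype == "protein_coding" and gene.gene_id in truth.retained:
            f = config.outron_background_fraction
            if treated and truth.retained[gene.gene_id]:
                f *= 2.0 ** truth.usage_shift[gene.gene_id]
            ow = _outron_interval(gene)
            if ow is not None:
                lam[strand][ow.start : ow.end] = f * config.lambda_body
        if gene.gene_id in truth.antisense_upregulated and truth.antisense_upregulated[gene.gene_id]:
            # PROMPT-like divergent signal on the opposite strand upstream of the TSS
            a = config.antisense_base_fraction * config.lambda_body
            if treated:
                a *= 2.0**config.antisense_lfc
            w = config.antisense_window
            if gene.strand == "+":
                alo, ahi = max(0, gene.tss - w), gene.tss
                anti = "-"
            else:
                alo, ahi = gene.tss, min(size, gene.tss + w)
                anti = "+"
            if ahi > alo:
                lam[anti][alo:ahi] = np.maximum(lam[anti][alo:ahi], a)

    for el in annotation.regulatory:
        if el.class_label != "putative_enhancer":
            continue
        base = config.enhancer_base_fraction * config.lambda_body
        level = base
        if treated and truth.enhancer_upregulated.get(el.element_id, False):
            level = base * 2.0**config.enhancer_lfc
        for strand in ("+", "-"):
            seg = lam[strand][el.interval.start : el.interval.end]
            np.maximum(seg, level, out=seg)

    if treated:
        # termination-readthrough decay is added on top of whatever baseline
        # the corridor carries, truncated hard at the planted extent
        for gene in annotation:
            if gene.biotype != "snRNA":
                continue
            extent = truth.snrna_extent[gene.gene_id]
            d = np.arange(extent, dtype=float)
            decay = np.maximum(
                config.lambda_body * np.exp(-d / config.decay_tau),
                config.readthrough_floor * config.lambda_body,
            )
            lo = gene.tes
            hi = min(gene.tes + extent, size)
            lam["+"][lo:hi] += decay[: hi - lo]

    tracks = {}
    for strand in ("+", "-"):
        vals = rng.poisson(lam[strand]).astype(float)
        tracks[strand] = CoverageTrack(
            values={CHROM: vals},
            strand=strand,
            library_size=float(vals.sum()) / config.read_length,
        )
    return tracks


def simulate_condition_tracks(
    annotation: AnnotationSet, truth: GroundTruth, config: SimulationConfig
) -> dict[str, list[dict[str, CoverageTrack]]]:
    """All replicates for both conditions: {condition: [ {strand: track}, ... ]}."""
    return {
        cond: [
            simulate_tracks(annotation, truth, config, cond, rep)
            for rep in range(config.n_replicates)
        ]
        for cond in ("control", "treatment")
    }


# ---------------------------------------------------------------------------
# NB count matrices (2 genotypes x 2 treatments)
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """NB counts for a wt/mutant x control/rnai design with planted classes.

    Planted genes are downregulated by RNAi in the wild type
    (``beta_treatment`` log2); in the mutant the interaction coefficient
    either flips the combined effect's sign (reversed) or shrinks it while
    preserving sign (attenuated).  Null genes carry no effect.  Per-sample
    sequencing-depth factors are lognormal.
    """
    rng = _rng(config, 37)
    truth = GroundTruth()
    n = config.n_count_genes
    classes = (
        ["reversed"] * config.n_reversed
        + ["attenuated"] * config.n_attenuated
        + ["null"] * config.n_null
    )
    rng.shuffle(classes)
    gene_ids = [f"cg{i:04d}" for i in range(n)]

    b_t = np.zeros(n)
    b_i = np.zeros(n)
    for i, cls in enumerate(classes):
        if cls == "reversed":
            b_t[i] = config.beta_treatment
            b_i[i] = config.beta_interaction_reversed
        elif cls == "attenuated":
            b_t[i] = config.beta_treatment
            b_i[i] = config.beta_interaction_attenuated
        truth.count_class[gene_ids[i]] = cls
        truth.count_betas[gene_ids[i]] = (b_t[i], b_i[i])

    samples = []
    for genotype in ("wt", "mutant"):
        for treatment in ("control", "rnai"):
            for rep in range(config.n_reps_counts):
                samples.append((f"{genotype}_{treatment}_{rep + 1}", genotype, treatment, rep + 1))
    sheet = pd.DataFrame(samples, columns=["sample", "genotype", "treatment", "replicate"])

    depth = np.exp(rng.normal(0.0, config.depth_sd, size=len(sheet)))
    counts = np.zeros((n, len(sheet)), dtype=int)
    for s, row in sheet.iterrows():
        g = 1.0 if row.genotype == "mutant" else 0.0
        t = 1.0 if row.treatment == "rnai" else 0.0
        log2_mu = np.log2(config.counts_mean) + t * b_t + g * t * b_i
        mu = depth[s] * 2.0**log2_mu
        counts[:, s] = _nb_sample(rng, mu, config.dispersion)

    frame = pd.DataFrame(counts, index=gene_ids, columns=sheet["sample"].tolist())
    return frame, sheet, truth


# ---------------------------------------------------------------------------
# Small-RNA records and paired 22G/mRNA matrices
# ---------------------------------------------------------------------------

def simulate_smallrna(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Small-RNA read records plus paired 22G and mRNA count matrices.

    Returns (records, counts_22g, counts_mrna, sample_sheet, truth).  Planted
    target genes gain antisense 22G reads and lose mRNA signal under
    treatment; antisense read 5' nucleotides are G-biased.
    """
    rng = _rng(config, 53)
    truth = GroundTruth()
    n = config.n_smallrna_genes
    gene_ids = [f"sg{i:04d}" for i in range(n)]
    target_idx = set(rng.choice(n, size=config.n_targets, replace=False).tolist())
    for i, gid in enumerate(gene_ids):
        truth.target_22g[gid] = i in target_idx

    samples = []
    for treatment in ("control", "treatment"):
        for rep in range(config.n_reps_counts):
            samples.append((f"{treatment}_{rep + 1}", "wt", treatment, rep + 1))
    sheet = pd.DataFrame(samples, columns=["sample", "genotype", "treatment", "replicate"])

    c22 = np.zeros((n, len(sheet)), dtype=int)
    cmr = np.zeros((n, len(sheet)), dtype=int)
    lfc22 = np.array([config.target_22g_lfc if i in target_idx else 0.0 for i in range(n)])
    lfcmr = np.array([config.target_mrna_lfc if i in target_idx else 0.0 for i in range(n)])
    for s, row in sheet.iterrows():
        t = 1.0 if row.treatment == "treatment" else 0.0
        mu22 = config.smallrna_mean * 2.0 ** (t * lfc22)
        mumr = config.counts_mean * 2.0 ** (t * lfcmr)
        c22[:, s] = _nb_sample(rng, mu22, config.smallrna_dispersion)
        cmr[:, s] = _nb_sample(rng, mumr, config.dispersion)

    counts_22g = pd.DataFrame(c22, index=gene_ids, columns=sheet["sample"].tolist())
    counts_mrna = pd.DataFrame(cmr, index=gene_ids, columns=sheet["sample"].tolist())

    # read-level records: antisense siRNA reads over coding genes, sense miRNA reads
    n_anti = int(config.n_reads * 0.8)
    n_mir = config.n_reads - n_anti
    records = []
    lengths = rng.choice([20, 21, 22, 23, 24], size=n_anti, p=[0.05, 0.15, 0.6, 0.15, 0.05])
    for r in range(n_anti):
        gid = gene_ids[int(rng.integers(n))]
        if rng.random() < config.g_bias:
            nt = "G"
        else:
            nt = str(rng.choice(["A", "C", "U"]))
        records.append((f"r{r:05d}", int(lengths[r]), nt, "antisense", gid, "protein_coding"))
    for r in range(n_mir):
        mid = f"mir{int(rng.integers(config.n_mirna)):02d}"
        nt = str(rng.choice(["A", "C", "G", "U"]))
        length = int(rng.integers(21, 24))
        records.append((f"m{r:05d}", length, nt, "sense", mid, "miRNA"))
    rec_frame = pd.DataFrame(
        records,
        columns=["read_id", "length", "first_nt", "strand_rel", "feature_id", "feature_biotype"],
    )
    return rec_frame, counts_22g, counts_mrna, sheet, truth


# ---------------------------------------------------------------------------
# Synthetic ChIP peaks (for the annotation module)
# ---------------------------------------------------------------------------

def simulate_peaks(
    annotation: AnnotationSet, config: SimulationConfig, n_peaks: int = 200
) -> pd.DataFrame:
    """Random narrowPeak-style peaks over the toy chromosome.

    Peaks are dropped near TSSs, inside gene bodies and in intergenic space
    so that every assignment category occurs.
    """
    rng = _rng(config, 71)
    size = annotation.chrom_sizes[CHROM]
    genes = [g for g in annotation if g.biotype == "protein_coding"]
    rows = []
    for i in range(n_peaks):
        mode = rng.random()
        width = int(rng.integers(150, 400))
        if mode < 0.4 and genes:
            g = genes[int(rng.integers(len(genes)))]
            center = int(g.tss + rng.integers(-200, 201))
        elif mode < 0.7 and genes:
            g = genes[int(rng.integers(len(genes)))]
            center = int(rng.integers(g.span.start, g.span.end))
        else:
            center = int(rng.integers(1000, size - 1000))
        start = max(0, center - width // 2)
        end = start + width
        rows.append(
            (
                CHROM,
                start,
                end,
                f"peak{i:04d}",
                int(rng.integers(100, 1000)),
                ".",
                float(rng.uniform(2, 50)),
                float(rng.uniform(3, 20)),
                float(rng.uniform(2, 15)),
                width // 2,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "summit",
        ],
    )


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", header=False, index=False)
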