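"""End-to-end orchestration: simulate -> measure -> classify -> report.

``run_pipeline`` drives every analysis stage over the synthetic genome and
writes one TSV per stage plus a JSON summary and a machine-readable run
manifest.  Outputs are a pure function of the configuration: every file
carries the config hash in a header comment and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import diff_stats, outron_analysis, peak_annotation, synthetic_data
from . import termination_readthrough as tr
from .coverage_engine import write_bedgraph
from .genome_model import eligible_outron_genes, write_gtf, write_regulatory_bed
from .synthetic_data import SimulationConfig

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Pipeline parameters; defaults are the published analysis settings."""

    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)

    # outron analysis
    outron_window: int = 150
    pseudocount: float = 0.01
    outron_lfc: float = 0.58
    min_body_density: float = 0.1
    min_outron_density: float = 0.01
    min_outron_reads: float = 5.0

    # readthrough
    readthrough_bin: int = 100
    readthrough_max_extent: int = 15000
    readthrough_rel_threshold: float = 0.1

    # metagene
    metagene_flank: int = 1000
    metagene_body: int = 1000
    metagene_bin: int = 10

    # peak annotation
    proximity_window: int = 300
    tss_tes_halfwidth: int = 100

    # differential expression
    de_padj: float = 0.05
    de_lfc: float = 1.0
    interaction_fdr: float = 0.05
    interaction_lfc: float = 0.5
    antisense_lfc_threshold: float = 1.0
    antisense_min_density: float = 0.1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in data.pop("sim", {}).items()
        })
        return cls(sim=sim, **data)


def load_tracks_manifest(path) -> dict:
    """Load {condition: [{strand: CoverageTrack}, ...]} from a manifest TSV.

    Columns: condition, replicate, strand, path (relative to the manifest).
    """
    from .coverage_engine import read_bedgraph

    path = Path(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    tracks: dict = {}
    for cond, group in table.groupby("condition"):
        reps = []
        for _, rep_group in group.groupby("replicate"):
            stranded = {}
            for row in rep_group.itertuples():
                p = Path(row.path)
                if not p.is_absolute():
                    p = path.parent / p
                stranded[row.strand] = read_bedgraph(p, strand=row.strand)
            reps.append(stranded)
        tracks[cond] = reps
    return tracks


def _write_tsv(frame: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on the synthetic genome; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash()} seed={config.sim.seed}"
    sim = config.sim

    log.info("simulating genome (seed=%d)", sim.seed)
    annotation, truth = synthetic_data.build_genome(sim)
    write_gtf(annotation, outdir / "annotation.gtf")
    write_regulatory_bed(annotation.regulatory, outdir / "regulatory.bed")
    _write_tsv(truth.to_frame(), outdir / "ground_truth.tsv", tag)

    tracks = synthetic_data.simulate_condition_tracks(annotation, truth, sim)
    manifest_rows = []
    for cond, reps in tracks.items():
        for r, rep in enumerate(reps):
            for strand_name, strand in (("fwd", "+"), ("rev", "-")):
                p = outdir / f"coverage_{cond}_rep{r + 1}_{strand_name}.bedgraph"
                write_bedgraph(rep[strand], p)
                manifest_rows.append((cond, r + 1, strand, p.name))
    pd.DataFrame(
        manifest_rows, columns=["condition", "replicate", "strand", "path"]
    ).to_csv(outdir / "tracks_manifest.tsv", sep="\t", index=False)

    # --- outron retention ---
    eligible = sorted(eligible_outron_genes(annotation))
    measurements = outron_analysis.analyze_outrons(
        annotation, tracks, eligible,
        window=config.outron_window, pseudocount=config.pseudocount,
        read_length=sim.read_length,
    )
    increased, decreased, outron_table = outron_analysis.call_differential_outrons(
        measurements,
        min_body=config.min_body_density,
        min_outron=config.min_outron_density,
        min_reads=config.min_outron_reads,
        lfc_threshold=config.outron_lfc,
    )
    _write_tsv(outron_table, outdir / "outron_table.tsv", tag)

    # --- termination readthrough ---
    calls, effects = tr.profile_noncoding_loci(
        annotation, tracks,
        bin_size=config.readthrough_bin,
        max_extent=config.readthrough_max_extent,
        rel_threshold=config.readthrough_rel_threshold,
    )
    call_table = pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "distance": c.distance,
                "window_start": c.window.start if c.window else "",
                "window_end": c.window.end if c.window else "",
                "body_mean_treatment": c.body_mean_treatment,
            }
            for c in calls
        ]
    )
    _write_tsv(call_table, outdir / "readthrough_calls.tsv", tag)
    _write_tsv(effects, outdir / "readthrough_gene_effects.tsv", tag)

    # --- promoter antisense ---
    anti_rows = [
        tr.promoter_antisense(
            annotation.genes[gid], tracks,
            lfc_threshold=config.antisense_lfc_threshold,
            min_density=config.antisense_min_density,
        )
        for gid in eligible
    ]
    anti_table = pd.DataFrame(anti_rows)
    _write_tsv(anti_table, outdir / "promoter_antisense.tsv", tag)

    # --- peak annotation ---
    peaks_frame = synthetic_data.simulate_peaks(annotation, sim)
    synthetic_data.write_narrowpeak(peaks_frame, outdir / "peaks.narrowPeak")
    peaks = peak_annotation.read_narrowpeak(outdir / "peaks.narrowPeak")
    assignments = peak_annotation.assign_peaks(
        peaks, annotation.regulatory, annotation, config.tss_tes_halfwidth
    )
    assignments = peak_annotation.flag_intronic_proximal(
        assignments, peaks, annotation, config.proximity_window
    )
    bound = peak_annotation.bound_genes(assignments, annotation.regulatory)
    _write_tsv(
        peak_annotation.assignments_to_frame(assignments),
        outdir / "peak_assignments.tsv", tag,
    )

    # --- counts: DE and interaction classes ---
    counts, sheet, counts_truth = synthetic_data.simulate_counts(sim)
    _write_tsv(counts, outdir / "counts.tsv", tag, index=True)
    _write_tsv(sheet, outdir / "samples.tsv", tag)
    wt = sheet[sheet.genotype == "wt"]
    de = diff_stats.nb_wald_de(
        counts[wt["sample"]], wt["treatment"].to_numpy(), reference="control"
    )
    de["significant"] = (de["padj"] <= config.de_padj) & (
        de["log2fc"].abs() >= config.de_lfc
    )
    _write_tsv(de, outdir / "de_wt.tsv", tag, index=True)
    model = diff_stats.nb_interaction_model(counts, sheet)
    classes = diff_stats.classify_interaction(
        model, fdr=config.interaction_fdr, lfc=config.interaction_lfc
    )
    _write_tsv(classes, outdir / "interaction_classes.tsv", tag, index=True)

    # --- small RNA ---
    records, c22, cmr, sm_sheet, sm_truth = synthetic_data.simulate_smallrna(sim)
    records = records.assign(read_class=diff_stats.classify_reads(records))
    _write_tsv(records, outdir / "smallrna_records.tsv", tag)
    de22 = diff_stats.nb_wald_de(c22, sm_sheet["treatment"].to_numpy(), reference="control")
    demr = diff_stats.nb_wald_de(cmr, sm_sheet["treatment"].to_numpy(), reference="control")
    targets = diff_stats.call_22g_targets(de22, demr, padj=config.de_padj)
    _write_tsv(targets, outdir / "smallrna_targets.tsv", tag, index=True)

    # --- summary ---
    distance_strata = {
        "le_5kb": int(sum(0 < c.distance <= 5000 for c in calls)),
        "le_15kb": int(sum(0 < c.distance <= 15000 for c in calls)),
    }
    class_counts = classes["class"].value_counts().to_dict()
    summary = {
        "config_hash": config.config_hash(),
        "seed": sim.seed,
        "n_genes": len(annotation),
        "n_eligible": len(eligible),
        "outron_increased": len(increased),
        "outron_decreased": len(decreased),
        "readthrough_loci": distance_strata,
        "peak_categories": (
            peak_annotation.assignments_to_frame(assignments)["category"]
            .value_counts().to_dict()
        ),
        "bound_genes": len(bound),
        "de_significant": int(de["significant"].sum()),
        "antisense_upregulated": int(anti_table["upregulated"].sum()) if len(anti_table) else 0,
        "interaction_classes": {k: int(v) for k, v in class_counts.items()},
        "smallrna_targets": int(targets["candidate"].sum()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(
            {"config": config.to_dict(), "config_hash": config.config_hash(),
             "seed": sim.seed},
            fh, indent=2, sort_keys=True, default=str,
        )
        fh.write("\n")
    return summary
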