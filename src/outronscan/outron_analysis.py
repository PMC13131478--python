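"""Outron (un-trans-spliced 5' region) usage and differential retention calls.

For each eligible gene the mean coverage density over a 150 bp window
immediately upstream of the TSS is compared to the density over the
representative transcript's exonic body.  Usage is the pseudocounted ratio

    usage = (outron_density + eps) / (body_density + eps),  eps = 0.01

and differential retention between two conditions is the log2 ratio of the
replicate-mean usages.  Genes whose upstream region carries invading
transcription (readthrough from a neighbouring locus) are flagged by a
regression-slope score over sequential upstream windows and excluded from
high-confidence calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage_engine import CoverageTrack
from .genome_model import AnnotationSet, GeneModel, GenomicInterval

log = logging.getLogger(__name__)

# tracks for one condition: one {strand: CoverageTrack} mapping per replicate
ConditionTracks = Sequence[Mapping[str, CoverageTrack]]


@dataclass
class OutronMeasurement:
    gene_id: str
    outron_density: dict[str, np.ndarray]  # condition -> per-replicate values
    body_density: dict[str, np.ndarray]
    usage: dict[str, np.ndarray]
    outron_reads: dict[str, float]  # condition-level, pooled over replicates
    log2_delta_usage: float
    readthrough_slope: dict[str, float] = field(default_factory=dict)
    far_upstream_mean: dict[str, float] = field(default_factory=dict)
    passed_coverage: bool = False
    readthrough_excluded: bool = False
    differential: bool = False


def outron_window(gene: GeneModel, window: int = 150) -> GenomicInterval | None:
    """The [tss - window, tss) interval, strand-aware, clipped at the contig start."""
    if gene.strand == "+":
        lo, hi = gene.tss - window, gene.tss
    else:
        lo, hi = gene.tss, gene.tss + window
    lo = max(lo, 0)
    if hi <= lo:
        return None
    return GenomicInterval(gene.chrom, lo, hi, gene.strand)


def body_intervals(gene: GeneModel, mode: str = "exons") -> list[GenomicInterval]:
    """Gene-body intervals: representative-transcript exon union, or full span."""
    if mode == "span":
        return [gene.span]
    return list(gene.representative.exons)


def _multi_interval_mean(track: CoverageTrack, intervals: Sequence[GenomicInterval]) -> float:
    total = 0.0
    length = 0
    for iv in intervals:
        total += track.sum(iv)
        length += len(iv)
    return total / length if length else 0.0


def measure_outron(
    gene: GeneModel,
    tracks: Mapping[str, ConditionTracks],
    window: int = 150,
    pseudocount: float = 0.01,
    read_length: int = 40,
    body_mode: str = "exons",
    control: str = "control",
    treatment: str = "treatment",
) -> OutronMeasurement:
    """Per-replicate outron/body densities and the usage shift for one gene.

    ``tracks`` maps condition name to a sequence of per-replicate
    {strand: CoverageTrack} mappings; only the gene's sense strand is read.
    """
    ow = outron_window(gene, window)
    body = body_intervals(gene, body_mode)
    od: dict[str, np.ndarray] = {}
    bd: dict[str, np.ndarray] = {}
    usage: dict[str, np.ndarray] = {}
    reads: dict[str, float] = {}
    for cond, reps in tracks.items():
        o_vals, b_vals, read_sum = [], [], 0.0
        for rep in reps:
            track = rep[gene.strand]
            o = track.mean(ow) if ow is not None else 0.0
            b = _multi_interval_mean(track, body)
            o_vals.append(o)
            b_vals.append(b)
            if ow is not None:
                read_sum += track.sum(ow) / read_length
        od[cond] = np.asarray(o_vals)
        bd[cond] = np.asarray(b_vals)
        usage[cond] = (od[cond] + pseudocount) / (bd[cond] + pseudocount)
        reads[cond] = read_sum
    u_t = float(usage[treatment].mean())
    u_c = float(usage[control].mean())
    log2_delta = float(np.log2(u_t / u_c))
    return OutronMeasurement(
        gene_id=gene.gene_id,
        outron_density=od,
        body_density=bd,
        usage=usage,
        outron_reads=reads,
        log2_delta_usage=log2_delta,
    )


def upstream_readthrough_score(
    gene: GeneModel,
    track: CoverageTrack,
    n_windows: int = 6,
    window_bp: int = 50,
    outron_window_bp: int = 150,
) -> tuple[float, float]:
    """Regression-slope readthrough score over sequential upstream windows.

    ``n_windows`` windows of ``window_bp`` tile the region immediately 5' of
    the outron window.  Returns (slope, mean): the OLS slope of window mean
    density against the distance from the TSS to the window centre, and the
    mean density over all windows.  A positive slope, or a high flat profile,
    marks transcription invading from upstream.
    """
    densities = []
    distances = []
    any_on_contig = False
    for j in range(n_windows):
        dist_near = outron_window_bp + j * window_bp
        dist_far = dist_near + window_bp
        if gene.strand == "+":
            lo, hi = gene.tss - dist_far, gene.tss - dist_near
        else:
            lo, hi = gene.tss + dist_near, gene.tss + dist_far
        lo_c = max(lo, 0)
        if hi <= lo_c:
            continue
        any_on_contig = True
        iv = GenomicInterval(gene.chrom, lo_c, hi, gene.strand)
        densities.append(track.mean(iv))
        distances.append(dist_near + window_bp / 2.0)
    if not any_on_contig or len(densities) < 2:
        log.warning("gene %s: upstream regression windows off-contig", gene.gene_id)
        return 0.0, float(np.mean(densities)) if densities else 0.0
    x = np.asarray(distances)
    y = np.asarray(densities)
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, float(y.mean())


def readthrough_exclusion(
    slope: float, far_mean: float, body_density: float
) -> bool:
    """Exclude when upstream signal invades (rising) or saturates the window."""
    if slope > 0 and far_mean > 0.5 * body_density:
        return True
    return far_mean >= body_density > 0


def analyze_outrons(
    annotation: AnnotationSet,
    tracks: Mapping[str, ConditionTracks],
    gene_ids: Sequence[str] | None = None,
    window: int = 150,
    pseudocount: float = 0.01,
    read_length: int = 40,
    body_mode: str = "exons",
    control: str = "control",
    treatment: str = "treatment",
) -> list[OutronMeasurement]:
    """Measure every (eligible) gene and attach readthrough-exclusion flags."""
    from .genome_model import eligible_outron_genes

    if gene_ids is None:
        gene_ids = sorted(eligible_outron_genes(annotation))
    out: list[OutronMeasurement] = []
    for gid in gene_ids:
        gene = annotation.genes[gid]
        m = measure_outron(
            gene, tracks, window, pseudocount, read_length, body_mode, control, treatment
        )
        excluded = False
        for cond, reps in tracks.items():
            slopes, fars = [], []
            for rep in reps:
                s, f = upstream_readthrough_score(gene, rep[gene.strand], outron_window_bp=window)
                slopes.append(s)
                fars.append(f)
            m.readthrough_slope[cond] = float(np.mean(slopes))
            m.far_upstream_mean[cond] = float(np.mean(fars))
            body = float(m.body_density[cond].mean())
            if readthrough_exclusion(m.readthrough_slope[cond], m.far_upstream_mean[cond], body):
                excluded = True
        m.readthrough_excluded = excluded
        out.append(m)
    return out


def call_differential_outrons(
    measurements: Sequence[OutronMeasurement],
    min_body: float = 0.1,
    min_outron: float = 0.01,
    min_reads: float = 5.0,
    lfc_threshold: float = 0.58,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Differential outron-retention calls (thresholds inclusive).

    A gene passes coverage when, in at least one condition, body density
    >= ``min_body``, outron density >= ``min_outron`` and the pooled outron
    read estimate >= ``min_reads``.  High-confidence increased calls further
    require no readthrough exclusion and log2 usage shift >= ``lfc_threshold``;
    decreased calls (<= -threshold) are reported separately.
    """
    rows = []
    increased: list[str] = []
    decreased: list[str] = []
    for m in measurements:
        passed = any(
            m.body_density[c].mean() >= min_body
            and m.outron_density[c].mean() >= min_outron
            and m.outron_reads[c] >= min_reads
            for c in m.body_density
        )
        m.passed_coverage = passed
        m.differential = (
            passed and not m.readthrough_excluded and m.log2_delta_usage >= lfc_threshold
        )
        if m.differential:
            increased.append(m.gene_id)
        if passed and not m.readthrough_excluded and m.log2_delta_usage <= -lfc_threshold:
            decreased.append(m.gene_id)
        row = {"gene_id": m.gene_id, "log2_delta_usage": m.log2_delta_usage}
        for cond in m.body_density:
            row[f"outron_density_{cond}"] = float(m.outron_density[cond].mean())
            row[f"body_density_{cond}"] = float(m.body_density[cond].mean())
            row[f"usage_{cond}"] = float(m.usage[cond].mean())
            row[f"outron_reads_{cond}"] = m.outron_reads[cond]
            row[f"readthrough_slope_{cond}"] = m.readthrough_slope.get(cond, np.nan)
        row["passed_coverage"] = m.passed_coverage
        row["readthrough_excluded"] = m.readthrough_excluded
        row["differential"] = m.differential
        rows.append(row)
    table = pd.DataFrame(rows)
    n_unfiltered = (
        int((table["log2_delta_usage"] >= lfc_threshold).sum()) if len(table) else 0
    )
    log.info(
        "differential outrons: %d increased (high-confidence), %d decreased, "
        "%d unfiltered >= threshold, %d genes measured",
        len(increased), len(decreased), n_unfiltered, len(table),
    )
    return increased, decreased, table
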