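"""Transcription-termination readthrough at snRNA/snoRNA loci.

Integrator-dependent loci that fail to terminate produce coverage running
past the annotated TES.  This module profiles that signal (gene-body
normalised bins for heatmaps), estimates how far the readthrough extends,
and quantifies its interference with genes inside the readthrough window.
It also measures promoter-upstream antisense (PROMPT-like) signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage_engine import CoverageTrack
from .genome_model import AnnotationSet, GeneModel, GenomicInterval
from .outron_analysis import ConditionTracks

log = logging.getLogger(__name__)


@dataclass
class ReadthroughProfile:
    locus_id: str
    body_mean: float
    bins: np.ndarray  # upstream bins then downstream bins, body-normalised
    n_upstream: int
    bin_size: int


@dataclass
class ReadthroughCall:
    locus_id: str
    distance: int
    window: GenomicInterval | None  # None when distance == 0
    body_mean_treatment: float


def _downstream_interval(locus: GeneModel, offset: int, width: int) -> GenomicInterval | None:
    """Interval ``offset``..``offset+width`` bp past the TES in the direction of transcription."""
    if locus.strand == "+":
        lo, hi = locus.tes + offset, locus.tes + offset + width
    else:
        lo, hi = locus.tes - offset - width, locus.tes - offset
    lo = max(lo, 0)
    if hi <= lo:
        return None
    return GenomicInterval(locus.chrom, lo, hi, locus.strand)


def tes_profile(
    locus: GeneModel,
    track: CoverageTrack,
    window: int = 500,
    bin_size: int = 10,
    upstream: int = 100,
) -> ReadthroughProfile | None:
    """Body-normalised coverage bins around the TES.

    ``upstream`` bp inside the gene body (showing the normalised body level)
    followed by ``window`` bp downstream, in ``bin_size`` bins, all divided
    by the locus body mean.  Returns None (with a warning) if the body mean
    is zero.
    """
    body_mean = track.mean(locus.span)
    if body_mean <= 0:
        log.warning("locus %s has zero body coverage; skipped", locus.gene_id)
        return None
    n_up = upstream // bin_size
    n_down = window // bin_size
    bins = np.empty(n_up + n_down)
    for j in range(n_up):
        iv = _downstream_interval(locus, -(upstream - j * bin_size), bin_size)
        bins[j] = track.mean(iv) if iv is not None else 0.0
    for j in range(n_down):
        iv = _downstream_interval(locus, j * bin_size, bin_size)
        bins[n_up + j] = track.mean(iv) if iv is not None else 0.0
    return ReadthroughProfile(locus.gene_id, body_mean, bins / body_mean, n_up, bin_size)


def estimate_readthrough_distance(
    locus: GeneModel,
    track_treatment: CoverageTrack,
    track_control: CoverageTrack,
    bin_size: int = 100,
    max_extent: int = 15000,
    rel_threshold: float = 0.1,
    fold_over_control: float = 2.0,
) -> ReadthroughCall:
    """Walk downstream of the TES and find the extent of the readthrough run.

    A bin counts as read-through when treatment density is at least
    ``rel_threshold`` of the treatment body mean AND exceeds
    ``fold_over_control`` times the control density there — requiring both
    absolute and differential evidence avoids calling constitutively
    expressed downstream genes.  The distance is the end of the maximal
    contiguous run starting at the TES (0 if the first bin already fails).
    """
    body_mean = track_treatment.mean(locus.span)
    distance = 0
    n_bins = max_extent // bin_size
    for k in range(n_bins):
        iv = _downstream_interval(locus, k * bin_size, bin_size)
        if iv is None:
            break
        t = track_treatment.mean(iv)
        c = track_control.mean(iv)
        if t >= rel_threshold * body_mean and t > fold_over_control * c:
            distance = (k + 1) * bin_size
        else:
            break
    window = None
    if distance > 0:
        if locus.strand == "+":
            window = GenomicInterval(locus.chrom, locus.tes, locus.tes + distance, "+")
        else:
            window = GenomicInterval(locus.chrom, max(0, locus.tes - distance), locus.tes, "-")
    return ReadthroughCall(locus.gene_id, distance, window, float(body_mean))


def readthrough_window_gene_effects(
    call: ReadthroughCall,
    annotation: AnnotationSet,
    tracks: Mapping[str, ConditionTracks],
    pseudocount: float = 0.01,
    control: str = "control",
    treatment: str = "treatment",
) -> pd.DataFrame:
    """Quantify every gene intersecting the readthrough window, both strands.

    Each gene is measured over its span on its own sense strand: replicate-
    mean body density per condition and the pseudocounted log2 ratio.
    """
    columns = ["locus_id", "gene_id", "strand", f"density_{control}",
               f"density_{treatment}", "log2_ratio"]
    if call.window is None:
        return pd.DataFrame(columns=columns)
    rows = []
    for gene in annotation.overlapping(call.window):
        if gene.gene_id == call.locus_id:
            continue
        dens = {}
        for cond, reps in tracks.items():
            vals = [rep[gene.strand].mean(gene.span) for rep in reps]
            dens[cond] = float(np.mean(vals))
        ratio = float(
            np.log2((dens[treatment] + pseudocount) / (dens[control] + pseudocount))
        )
        rows.append(
            {
                "locus_id": call.locus_id,
                "gene_id": gene.gene_id,
                "strand": gene.strand,
                f"density_{control}": dens[control],
                f"density_{treatment}": dens[treatment],
                "log2_ratio": ratio,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def promoter_antisense(
    gene: GeneModel,
    tracks: Mapping[str, ConditionTracks],
    window: int = 400,
    pseudocount: float = 0.01,
    lfc_threshold: float = 1.0,
    min_density: float = 0.1,
    control: str = "control",
    treatment: str = "treatment",
) -> dict:
    """Promoter-upstream antisense density per condition and upregulation flag.

    Antisense signal is the opposite-strand coverage over [tss - window, tss)
    (strand-aware).  The gene is flagged antisense-upregulated when the
    pseudocounted log2 ratio is >= ``lfc_threshold`` and the treatment
    density reaches ``min_density``.
    """
    anti = "-" if gene.strand == "+" else "+"
    if gene.strand == "+":
        lo, hi = max(0, gene.tss - window), gene.tss
    else:
        lo, hi = gene.tss, gene.tss + window
    dens = {}
    for cond, reps in tracks.items():
        if hi <= lo:
            dens[cond] = 0.0
            continue
        iv = GenomicInterval(gene.chrom, lo, hi)
        dens[cond] = float(np.mean([rep[anti].mean(iv) for rep in reps]))
    ratio = float(np.log2((dens[treatment] + pseudocount) / (dens[control] + pseudocount)))
    return {
        "gene_id": gene.gene_id,
        f"antisense_density_{control}": dens[control],
        f"antisense_density_{treatment}": dens[treatment],
        "log2_ratio": ratio,
        "upregulated": ratio >= lfc_threshold and dens[treatment] >= min_density,
    }


def profile_noncoding_loci(
    annotation: AnnotationSet,
    tracks: Mapping[str, ConditionTracks],
    biotypes: tuple[str, ...] = ("snRNA",),
    control: str = "control",
    treatment: str = "treatment",
    **distance_kwargs,
) -> tuple[list[ReadthroughCall], pd.DataFrame]:
    """Estimate readthrough for every locus of the given biotypes.

    Replicates are averaged by averaging per-bin densities implicitly through
    a pooled mean track view: distances are estimated per replicate and the
    median taken, which is robust to a single noisy replicate.
    """
    calls: list[ReadthroughCall] = []
    effects = []
    for gene in sorted(annotation, key=lambda g: g.gene_id):
        if gene.biotype not in biotypes:
            continue
        per_rep = []
        for rep_t, rep_c in zip(tracks[treatment], tracks[control]):
            per_rep.append(
                estimate_readthrough_distance(
                    gene, rep_t[gene.strand], rep_c[gene.strand], **distance_kwargs
                )
            )
        distances = sorted(c.distance for c in per_rep)
        med = distances[len(distances) // 2]
        chosen = next(c for c in per_rep if c.distance == med)
        calls.append(chosen)
        eff = readthrough_window_gene_effects(chosen, annotation, tracks,
                                              control=control, treatment=treatment)
        if len(eff):
            effects.append(eff)
    table = (
        pd.concat(effects, ignore_index=True)
        if effects
        else readthrough_window_gene_effects(
            ReadthroughCall("", 0, None, 0.0), annotation, tracks,
            control=control, treatment=treatment,
        )
    )
    return calls, table
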