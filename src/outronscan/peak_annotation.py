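"""Two-tier hierarchical annotation of ChIP peaks and bound-gene sets.

Tier 1 assigns a peak to the regulatory element (promoter/enhancer map) with
the greatest base-pair overlap; tier 2 falls back to the gene with greatest
span overlap, classifying the peak by feature priority TSS > TES > exon >
intron, where TSS/TES are +/-100 bp point windows.  Peaks overlapping
nothing are intergenic.  Every peak receives exactly one assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .genome_model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    RegulatoryElement,
)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    name: str
    score: int = 0
    signal: float = 0.0
    pvalue: float = -1.0
    qvalue: float = -1.0
    summit: int = 0  # offset from start

    def __post_init__(self) -> None:
        if not (0 <= self.summit < len(self.interval)):
            raise ValueError(f"peak {self.name}: summit offset out of range")


@dataclass(frozen=True)
class PeakAssignment:
    peak: str
    tier: str  # regulatory | genic | intergenic
    category: str  # regulatory class, or TSS/TES/exon/intron/intergenic
    feature_id: str | None
    overlap_bp: int
    opposite_strand_proximal: bool | None = None  # intronic peaks only


def read_narrowpeak(path) -> list[Peak]:
    """Read a narrowPeak (BED6+4) file; a -1 summit becomes the peak midpoint."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"line {lineno}: narrowPeak requires 10 fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            summit = int(f[9])
            if summit < 0:
                summit = (end - start) // 2
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end, f[5] if f[5] in "+-" else "."),
                    name=f[3],
                    score=int(f[4]),
                    signal=float(f[6]),
                    pvalue=float(f[7]),
                    qvalue=float(f[8]),
                    summit=summit,
                )
            )
    return peaks


def _feature_category(peak: Peak, gene: GeneModel, halfwidth: int) -> str:
    """Classify a genic peak by priority TSS > TES > exon > intron."""
    iv = peak.interval
    tss_win = GenomicInterval(gene.chrom, max(0, gene.tss - halfwidth), gene.tss + halfwidth)
    if iv.overlap_bp(tss_win) > 0:
        return "TSS"
    tes_win = GenomicInterval(gene.chrom, max(0, gene.tes - halfwidth), gene.tes + halfwidth)
    if iv.overlap_bp(tes_win) > 0:
        return "TES"
    if any(iv.overlap_bp(e) > 0 for e in gene.representative.exons):
        return "exon"
    return "intron"


def assign_peaks(
    peaks: Sequence[Peak],
    regulatory: Sequence[RegulatoryElement],
    annotation: AnnotationSet,
    tss_tes_halfwidth: int = 100,
) -> list[PeakAssignment]:
    """One assignment per peak by maximal overlap; regulatory tier first.

    Ties on overlap are broken by lexicographically smallest element/gene id,
    making the result independent of input ordering.
    """
    assignments: list[PeakAssignment] = []
    for peak in peaks:
        iv = peak.interval
        # tier 1: regulatory map
        best_el: RegulatoryElement | None = None
        best_ov = 0
        for el in regulatory:
            ov = iv.overlap_bp(el.interval)
            if ov > best_ov or (
                ov == best_ov and ov > 0 and best_el is not None
                and el.element_id < best_el.element_id
            ):
                best_el, best_ov = el, ov
        if best_el is not None and best_ov > 0:
            assignments.append(
                PeakAssignment(peak.name, "regulatory", best_el.class_label,
                               best_el.element_id, best_ov)
            )
            continue
        # tier 2: genic by maximal span overlap
        best_gene: GeneModel | None = None
        best_ov = 0
        for gene in annotation.overlapping(iv):
            ov = iv.overlap_bp(gene.span)
            if ov > best_ov or (
                ov == best_ov and ov > 0 and best_gene is not None
                and gene.gene_id < best_gene.gene_id
            ):
                best_gene, best_ov = gene, ov
        if best_gene is not None and best_ov > 0:
            category = _feature_category(peak, best_gene, tss_tes_halfwidth)
            assignments.append(
                PeakAssignment(peak.name, "genic", category, best_gene.gene_id, best_ov)
            )
        else:
            assignments.append(
                PeakAssignment(peak.name, "intergenic", "intergenic", None, 0)
            )
    return assignments


def _point_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance from a point to a half-open interval (0 when inside)."""
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


def flag_intronic_proximal(
    assignments: Sequence[PeakAssignment],
    peaks: Sequence[Peak],
    annotation: AnnotationSet,
    window: int = 300,
) -> list[PeakAssignment]:
    """Mark intronic peaks near an opposite-strand TSS/TES.

    An intronic assignment gains ``opposite_strand_proximal=True`` when a
    gene on the strand opposite the assigned gene has its TSS or TES within
    ``window`` bp (inclusive) of the peak interval.
    """
    by_name = {p.name: p for p in peaks}
    out: list[PeakAssignment] = []
    for a in assignments:
        if a.tier != "genic" or a.category != "intron":
            out.append(a)
            continue
        peak = by_name[a.peak]
        host = annotation.genes[a.feature_id]
        iv = peak.interval
        probe = GenomicInterval(
            iv.chrom, max(0, iv.start - window - 1), iv.end + window + 1
        )
        proximal = False
        for gene in annotation.overlapping(probe):
            if gene.strand == host.strand or gene.strand == ".":
                continue
            for pos in (gene.tss, gene.tes):
                if _point_distance(pos, iv) <= window:
                    proximal = True
        # genes whose span misses the probe but whose TSS/TES point is exactly
        # at the boundary are covered by the +/- (window + 1) expansion above
        out.append(replace(a, opposite_strand_proximal=proximal))
    return out


def bound_genes(
    assignments: Sequence[PeakAssignment],
    regulatory: Sequence[RegulatoryElement] = (),
) -> set[str]:
    """Genes with at least one assigned peak.

    Genic-tier assignments contribute directly; regulatory-tier assignments
    contribute only when the regulatory map links the element to a gene.
    """
    linked = {el.element_id: el.gene_id for el in regulatory if el.gene_id}
    bound: set[str] = set()
    for a in assignments:
        if a.tier == "genic" and a.feature_id is not None:
            bound.add(a.feature_id)
        elif a.tier == "regulatory" and a.feature_id in linked:
            bound.add(linked[a.feature_id])
    return bound


def assignments_to_frame(assignments: Sequence[PeakAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak": a.peak,
                "tier": a.tier,
                "category": a.category,
                "feature_id": a.feature_id if a.feature_id is not None else "",
                "overlap_bp": a.overlap_bp,
                "opposite_strand_proximal": (
                    "" if a.opposite_strand_proximal is None else a.opposite_strand_proximal
                ),
            }
            for a in assignments
        ]
    )
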