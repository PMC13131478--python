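"""Gene models, annotation parsing and gene-eligibility filters.

Coordinates are 0-based half-open everywhere inside the package; conversion
happens only at the GTF (1-based inclusive) and BED/bedGraph (0-based
half-open) boundaries.  A gene's TSS/TES are strand-aware: for a minus-strand
gene the TSS is the right (``end``) boundary of its span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")

REGULATORY_CLASSES = (
    "coding_promoter",
    "putative_enhancer",
    "ncRNA",
    "pseudogene_promoter",
    "unassigned_promoter",
    "undefined_regulatory",
)


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


class AnnotationValidationError(ValueError):
    """Raised when parsed features violate the annotation contracts."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: exons not sorted"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        first, last = self.exons[0], self.exons[-1]
        return GenomicInterval(first.chrom, first.start, last.end, self.strand)


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    strand: str
    span: GenomicInterval
    transcripts: tuple[TranscriptModel, ...]
    representative: TranscriptModel

    @property
    def tss(self) -> int:
        """5' end of the gene, strand-aware."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def tes(self) -> int:
        """3' end of the gene, strand-aware."""
        return self.span.end if self.strand == "+" else self.span.start

    @property
    def chrom(self) -> str:
        return self.span.chrom


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    class_label: str
    element_id: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in REGULATORY_CLASSES:
            raise ValueError(f"unknown regulatory class {self.class_label!r}")


class AnnotationSet:
    """Genes (with an interval index over spans) plus a regulatory-element map."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        regulatory: Sequence[RegulatoryElement] = (),
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationValidationError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g.gene_id
            )
        self.regulatory: list[RegulatoryElement] = list(regulatory)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes or {})

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        """All genes whose span intersects ``interval`` (strand-blind)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return sorted((self.genes[h.data] for h in hits), key=lambda g: g.gene_id)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field9))
    if not attrs:
        raise GtfParseError(f"line {lineno}: cannot parse attributes {field9!r}")
    return attrs


def parse_gtf(path) -> AnnotationSet:
    """Parse a GTF (1-based inclusive) into an :class:`AnnotationSet`.

    Requires ``gene``/``exon`` features (``transcript`` lines are optional)
    carrying ``gene_id``, ``transcript_id`` (exons) and ``gene_biotype``
    attributes.  Coordinates are converted to 0-based half-open.
    """
    gene_meta: dict[str, dict] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, dict] = {}
    declared_tx: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(f"line {lineno}: bad coordinates {start1}-{end1}")
            if strand not in VALID_STRANDS:
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attr_s, lineno)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")

            if feature == "gene":
                gene_meta[gene_id] = {
                    "biotype": attrs.get("gene_biotype", "other"),
                    "span": GenomicInterval(chrom, start, end, strand),
                }
            elif feature == "transcript":
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise GtfParseError(f"line {lineno}: transcript missing transcript_id")
                declared_tx.append(tx_id)
                tx_meta[tx_id] = {"gene_id": gene_id, "strand": strand}
            elif feature == "exon":
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise GtfParseError(f"line {lineno}: exon missing transcript_id")
                tx_meta.setdefault(tx_id, {"gene_id": gene_id, "strand": strand})
                tx_exons.setdefault(tx_id, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
            # other feature types (CDS, UTR, ...) are ignored

    for tx_id in declared_tx:
        if tx_id not in tx_exons:
            raise AnnotationValidationError(f"transcript {tx_id} has no exons")

    transcripts: dict[str, list[TranscriptModel]] = {}
    for tx_id, exons in tx_exons.items():
        meta = tx_meta[tx_id]
        exons = sorted(exons, key=lambda e: e.start)
        tx = TranscriptModel(tx_id, meta["gene_id"], meta["strand"], tuple(exons))
        transcripts.setdefault(meta["gene_id"], []).append(tx)

    genes: list[GeneModel] = []
    for gene_id, txs in sorted(transcripts.items()):
        meta = gene_meta.get(gene_id)
        txs = sorted(txs, key=lambda t: t.transcript_id)
        if meta is None:
            chrom = txs[0].exons[0].chrom
            strand = txs[0].strand
            span = GenomicInterval(
                chrom,
                min(t.span.start for t in txs),
                max(t.span.end for t in txs),
                strand,
            )
            biotype = "other"
        else:
            span, biotype = meta["span"], meta["biotype"]
        rep = select_representative_transcript(txs)
        genes.append(GeneModel(gene_id, biotype, span.strand, span, tuple(txs), rep))

    # genes declared without any transcript/exon lines: keep with a synthetic
    # single-exon transcript covering the span
    for gene_id, meta in sorted(gene_meta.items()):
        if gene_id in transcripts:
            continue
        span = meta["span"]
        tx = TranscriptModel(gene_id + ".t1", gene_id, span.strand, (span,))
        genes.append(
            GeneModel(gene_id, meta["biotype"], span.strand, span, (tx,), tx)
        )

    return AnnotationSet(genes)


def write_gtf(annotation: AnnotationSet, path) -> None:
    """Write gene/transcript/exon features in 1-based inclusive GTF."""
    with open(path, "w") as fh:
        for gene in sorted(annotation, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "outronscan",
                        "gene",
                        str(gene.span.start + 1),
                        str(gene.span.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                tattrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_biotype "{gene.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "outronscan",
                            "transcript",
                            str(tx.span.start + 1),
                            str(tx.span.end),
                            ".",
                            tx.strand,
                            ".",
                            tattrs,
                        ]
                    )
                    + "\n"
                )
                for exon in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "outronscan",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                tx.strand,
                                ".",
                                tattrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# BED6 regulatory map I/O; name column = class_label[:element_id[:gene_id]]
# ---------------------------------------------------------------------------

def read_regulatory_bed(path) -> list[RegulatoryElement]:
    elements: list[RegulatoryElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: BED6 requires 6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            parts = name.split(":")
            class_label = parts[0]
            element_id = parts[1] if len(parts) > 1 else f"elem{lineno}"
            gene_id = parts[2] if len(parts) > 2 else None
            elements.append(
                RegulatoryElement(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    class_label,
                    element_id,
                    gene_id,
                )
            )
    return elements


def write_regulatory_bed(elements: Sequence[RegulatoryElement], path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            name = el.class_label + ":" + el.element_id
            if el.gene_id:
                name += ":" + el.gene_id
            iv = el.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Representative-transcript selection and eligibility filters
# ---------------------------------------------------------------------------

def select_representative_transcript(
    transcripts: Sequence[TranscriptModel],
) -> TranscriptModel:
    """Transcript with maximal exonic length; ties broken by smallest id."""
    if not transcripts:
        raise ValueError("no transcripts to select from")
    return min(transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))


def _upstream_neighbour_within(
    annotation: AnnotationSet, gene: GeneModel, gap: int
) -> bool:
    """True if any other gene's span lies within ``gap`` bp 5' of the TSS.

    Both strands are considered: any transcription unit immediately upstream
    can spill reads into the outron window.  Distance is measured from the TSS
    to the nearest boundary of the other gene's span (0 for overlap).
    """
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = max(0, tss - gap), tss
    else:
        lo, hi = tss, tss + gap
    if hi <= lo:
        return False
    probe = GenomicInterval(gene.chrom, lo, hi)
    for other in annotation.overlapping(probe):
        if other.gene_id != gene.gene_id:
            return True
    # boundary exactly `gap` away (half-open probe misses it; "within" is inclusive)
    for other in annotation:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        if gene.strand == "+" and other.span.end == lo and lo == tss - gap:
            return True
        if gene.strand == "-" and other.span.start == hi and hi == tss + gap:
            return True
    return False


def eligible_outron_genes(
    annotation: AnnotationSet,
    min_exonic: int = 500,
    tss_overlap: int = 50,
    upstream_gap: int = 300,
) -> set[str]:
    """Protein-coding genes suitable for outron quantification.

    A gene passes when its representative transcript has exonic length
    >= ``min_exonic``, no other gene span intersects TSS +/- ``tss_overlap``,
    and no gene (either strand) lies within ``upstream_gap`` bp upstream of
    the TSS.
    """
    keep: set[str] = set()
    for gene in annotation:
        if gene.biotype != "protein_coding":
            continue
        if gene.representative.exonic_length < min_exonic:
            continue
        lo = max(0, gene.tss - tss_overlap)
        hi = gene.tss + tss_overlap + 1  # inclusive +/- window
        probe = GenomicInterval(gene.chrom, lo, hi)
        if any(o.gene_id != gene.gene_id for o in annotation.overlapping(probe)):
            continue
        if _upstream_neighbour_within(annotation, gene, upstream_gap):
            continue
        keep.add(gene.gene_id)
    return keep


def tss_isolated(
    annotation: AnnotationSet,
    gene: GeneModel,
    window: int = 300,
    same_strand_only: bool = True,
) -> bool:
    """True if no (same-strand) neighbour gene lies within ``window`` of the TSS.

    This is the metagene-input filter used to suppress tandem-gene artefacts.
    """
    lo = max(0, gene.tss - window)
    hi = gene.tss + window
    if hi <= lo:
        return True
    probe = GenomicInterval(gene.chrom, lo, hi)
    for other in annotation.overlapping(probe):
        if other.gene_id == gene.gene_id:
            continue
        if same_strand_only and other.strand != gene.strand:
            continue
        return False
    return True
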