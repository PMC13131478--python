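"""Hierarchical peak assignment, proximity flags and bound-gene sets."""

import numpy as np
import pytest

from outronscan.genome_model import (
    AnnotationSet,
    GenomicInterval,
    RegulatoryElement,
)
from outronscan.peak_annotation import (
    Peak,
    assign_peaks,
    bound_genes,
    flag_intronic_proximal,
    read_narrowpeak,
)

from conftest import make_gene


def peak(name, start, end, chrom="chrT"):
    return Peak(GenomicInterval(chrom, start, end), name=name)


def element(eid, start, end, label="coding_promoter", gene_id=None, chrom="chrT"):
    return RegulatoryElement(GenomicInterval(chrom, start, end), label, eid, gene_id)


EMPTY = AnnotationSet([])


class TestNarrowPeakReader:
    def test_reads_fields_and_summit(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chrT\t100\t400\tpk1\t500\t.\t12.5\t8.0\t6.0\t150\n"
                     "chrT\t900\t1100\tpk2\t200\t.\t3.0\t2.0\t1.5\t-1\n")
        peaks = read_narrowpeak(p)
        assert peaks[0].summit == 150 and peaks[0].qvalue == 6.0
        assert peaks[1].summit == 100  # -1 becomes the midpoint

    def test_summit_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Peak(GenomicInterval("chrT", 0, 100), name="bad", summit=100)


class TestAssignPeaks:
    def test_regulatory_tier_takes_maximal_overlap(self):
        pk = peak("p", 1000, 1200)
        regs = [element("prom", 1080, 1400), element("enh", 900, 1080,
                                                     label="putative_enhancer")]
        (a,) = assign_peaks([pk], regs, EMPTY)
        assert a.feature_id == "prom" and a.overlap_bp == 120
        assert a.category == "coding_promoter"

    def test_exonic_peak_without_regulatory_overlap(self):
        gene = make_gene("g", 1000, 3000)
        pk = peak("p", 1500, 1700)  # inside body, > 100 bp from TSS/TES
        (a,) = assign_peaks([pk], [], AnnotationSet([gene]))
        assert (a.tier, a.category, a.feature_id) == ("genic", "exon", "g")

    def test_equal_overlap_tie_broken_lexicographically(self):
        pk = peak("p", 1000, 1100)
        regs = [element("zeta", 1000, 1100), element("alpha", 1000, 1100)]
        (a,) = assign_peaks([pk], regs, EMPTY)
        assert a.feature_id == "alpha"

    def test_tss_priority_over_exon(self):
        gene = make_gene("g", 1000, 3000)
        pk = peak("p", 950, 1150)  # overlaps TSS window and exon
        (a,) = assign_peaks([pk], [], AnnotationSet([gene]))
        assert a.category == "TSS"

    def test_intronic_classification(self):
        exons = (GenomicInterval("chrT", 1000, 1400, "+"),
                 GenomicInterval("chrT", 2600, 3000, "+"))
        gene = make_gene("g", 1000, 3000, exons=exons)
        pk = peak("p", 1800, 2000)
        (a,) = assign_peaks([pk], [], AnnotationSet([gene]))
        assert a.category == "intron"

    def test_no_overlap_is_intergenic(self):
        (a,) = assign_peaks([peak("p", 100, 200)], [], EMPTY)
        assert a.tier == "intergenic" and a.feature_id is None


class TestIntronicProximity:
    def _setup(self, gap):
        exons = (GenomicInterval("chrT", 1000, 1400, "+"),
                 GenomicInterval("chrT", 6000, 6500, "+"))
        host = make_gene("host", 1000, 6500, exons=exons)
        pk = peak("p", 2000, 2300)
        # minus-strand gene whose TES (= span start) sits exactly `gap` bp right
        # of the peak's last base; its TSS lies 2 kb further, out of range
        other = make_gene("opp", 2299 + gap, 2299 + gap + 2000, strand="-")
        ann = AnnotationSet([host, other])
        assignments = assign_peaks([pk], [], ann)
        return flag_intronic_proximal(assignments, [pk], ann)

    def test_opposite_tss_within_300_is_flagged(self):
        (a,) = self._setup(250)
        assert a.category == "intron" and a.opposite_strand_proximal is True

    def test_boundary_300_inclusive_301_exclusive(self):
        (at_300,) = self._setup(300)
        assert at_300.opposite_strand_proximal is True
        (at_301,) = self._setup(301)
        assert at_301.opposite_strand_proximal is False

    def test_non_intronic_peak_flag_absent(self):
        gene = make_gene("g", 1000, 3000)
        assignments = assign_peaks([peak("p", 1500, 1700)], [], AnnotationSet([gene]))
        out = flag_intronic_proximal(assignments, [peak("p", 1500, 1700)],
                                     AnnotationSet([gene]))
        assert out[0].opposite_strand_proximal is None


class TestBoundGenes:
    def test_gene_with_multiple_peaks_appears_once(self):
        gene = make_gene("g", 1000, 3000)
        ann = AnnotationSet([gene])
        peaks = [peak("p1", 1500, 1700), peak("p2", 2000, 2200)]
        assignments = assign_peaks(peaks, [], ann)
        assert bound_genes(assignments) == {"g"}

    def test_only_intergenic_peaks_gives_empty_set(self):
        assignments = assign_peaks([peak("p", 100, 200)], [], EMPTY)
        assert bound_genes(assignments) == set()

    def test_regulatory_promoter_link_contributes_gene(self):
        regs = [element("prom", 900, 1000, gene_id="g")]
        assignments = assign_peaks([peak("p", 950, 1100)], regs, EMPTY)
        assert bound_genes(assignments, regs) == {"g"}
        # without the link the regulatory tier contributes nothing
        regs_unlinked = [element("prom", 900, 1000)]
        assignments = assign_peaks([peak("p", 950, 1100)], regs_unlinked, EMPTY)
        assert bound_genes(assignments, regs_unlinked) == set()


def brute_force_assign(pk, regs, genes, halfwidth=100):
    """Independent maximal-overlap oracle using plain loops."""
    def ov(a_start, a_end, b_start, b_end):
        return max(0, min(a_end, b_end) - max(a_start, b_start))

    iv = pk.interval
    best, best_ov = None, 0
    for el in sorted(regs, key=lambda e: e.element_id):
        o = ov(iv.start, iv.end, el.interval.start, el.interval.end)
        if o > best_ov:
            best, best_ov = el.element_id, o
    if best is not None:
        return ("regulatory", best)
    for g in sorted(genes, key=lambda g: g.gene_id):
        o = ov(iv.start, iv.end, g.span.start, g.span.end)
        if o > best_ov:
            best, best_ov = g.gene_id, o
    return ("genic", best) if best else ("intergenic", None)


class TestOracleEquivalence:
    def test_matches_brute_force_and_partitions(self):
        rng = np.random.default_rng(17)
        genes = []
        pos = 500
        for i in range(60):
            pos += int(rng.integers(200, 1500))
            length = int(rng.integers(300, 2500))
            genes.append(make_gene(f"g{i:03d}", pos, pos + length,
                                   strand="+" if rng.random() < 0.5 else "-"))
            pos += length
        regs = []
        for j in range(50):
            start = int(rng.integers(0, pos))
            regs.append(element(f"e{j:03d}", start, start + int(rng.integers(50, 400)),
                                label="putative_enhancer"))
        ann = AnnotationSet(genes)
        peaks = []
        for k in range(300):
            start = int(rng.integers(0, pos))
            peaks.append(peak(f"p{k:03d}", start, start + int(rng.integers(80, 600))))
        assignments = assign_peaks(peaks, regs, ann)
        assert len(assignments) == len(peaks)  # partition: one per peak
        assert len({a.peak for a in assignments}) == len(peaks)
        by_name = {a.peak: a for a in assignments}
        for pk in peaks:
            tier, feature = brute_force_assign(pk, regs, genes)
            a = by_name[pk.name]
            assert (a.tier, a.feature_id) == (tier, feature)

    def test_invariant_under_input_ordering(self):
        rng = np.random.default_rng(19)
        genes = [make_gene(f"g{i}", 1000 * i + 100, 1000 * i + 800) for i in range(20)]
        regs = [element(f"e{j}", 1500 * j, 1500 * j + 300, label="putative_enhancer")
                for j in range(10)]
        peaks = [peak(f"p{k}", int(rng.integers(0, 20000)), 0) for k in range(0)]
        peaks = []
        for k in range(100):
            s = int(rng.integers(0, 20000))
            peaks.append(peak(f"p{k}", s, s + 250))
        ann = AnnotationSet(genes)
        a1 = assign_peaks(peaks, regs, ann)
        shuffled_peaks = list(peaks)[::-1]
        a2 = assign_peaks(shuffled_peaks, list(regs)[::-1], ann)
        assert {(a.peak, a.tier, a.feature_id) for a in a1} == \
               {(a.peak, a.tier, a.feature_id) for a in a2}
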