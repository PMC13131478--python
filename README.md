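# outronscan

RNA-processing analytics for organisms that trans-splice. `outronscan`
detects **outron retention** — failure to replace a pre-mRNA's native 5′
region with the spliced leader — from strand-specific RNA-seq coverage,
quantifies **transcription-termination readthrough** at snRNA/SL-RNA loci
and its interference with downstream genes, annotates **ChIP peaks**
hierarchically against a regulatory-element map, and classifies small-RNA
(**22G**) targets and genotype × treatment expression reversals from count
matrices. It is aimed at nematode transcriptomics work in which defects in
non-coding RNA 3′-end formation (e.g. loss of the Integrator endonuclease)
propagate into trans-splicing, small-RNA and mitochondrial phenotypes.

A bundled synthetic-data generator produces genomes, coverage tracks, count
matrices and small-RNA records with known ground truth, so every estimator
in the package can be validated end to end.

## The statistics at the core

**Outron usage.** For each eligible protein-coding gene (representative
transcript with exonic length ≥ 500 bp, no neighbour within ±50 bp of the
TSS or 300 bp upstream), coverage density is measured over the 150 bp window
upstream of the TSS (*o*) and over the exonic gene body (*b*), and combined
with a pseudocount ε = 0.01:

    usage = (o + ε) / (b + ε)
    Δ = log2( usage_treatment / usage_control )

A gene is called differentially outron-retained when Δ ≥ 0.58, coverage
thresholds are met (body ≥ 0.1, outron ≥ 0.01, ≥ 5 outron reads in at least
one condition), and a regression-slope readthrough score over sequential
upstream windows shows no invading transcription.

**Readthrough distance.** Walking downstream of a non-coding locus's TES in
100 bp bins, a bin is read-through when treatment density ≥ 0.1 × the
locus's treatment body mean *and* exceeds 2× the control density; the
distance is the end of the maximal contiguous run (capped at 15 kb). Genes
inside the window are quantified on both strands with pseudocounted log2
ratios.

**Peak annotation.** Tier 1 assigns each peak to the regulatory element of
maximal base-pair overlap; tier 2 falls back to the gene of maximal overlap
with feature priority TSS > TES > exon > intron (TSS/TES = ±100 bp
windows); intronic peaks are flagged when an opposite-strand TSS/TES lies
within 300 bp.

**Count statistics.** Median-of-ratios size factors and Benjamini–Hochberg
FDR are implemented from first principles. Differential tests use a
lightweight per-gene negative-binomial log-link GLM (IRLS) with
method-of-moments dispersion moderated toward the across-gene mean, and
Wald t statistics. On top sit the 22G quadrant caller (22G up ∧ mRNA down,
both FDR < 0.05) and the genotype × treatment classifier
(reversed / attenuated / unchanged at FDR < 0.05, |log2FC| ≥ 0.5).

## Worked example

Run every stage on the default synthetic genome (60 isolated coding genes,
an snRNA cluster with planted readthrough extents of 1, 5 and 15 kb, and
1,000-gene count matrices with 100 reversed / 100 attenuated genes):

```bash
outronscan run-all --seed 7 --outdir demo/
```

which prints the run summary:

```json
{
  "antisense_upregulated": 13,
  "bound_genes": 62,
  "de_significant": 201,
  "interaction_classes": {
    "attenuated": 96, "not_candidate": 800, "reversed": 98, "unchanged": 6
  },
  "n_eligible": 64,
  "outron_increased": 17,
  "readthrough_loci": {"le_15kb": 3, "le_5kb": 2},
  "smallrna_targets": 50
}
```

Reading the numbers: 17 genes are called with increased outron usage (15
were planted, at a +1 log2 usage shift); all three snRNA loci show
readthrough, two within 5 kb and one reaching 15 kb; the interaction
classifier recovers 98 of 100 planted reversed and 96 of 100 attenuated
genes; and all 50 planted 22G targets are called. Per-stage tables land in
`demo/` (`outron_table.tsv`, `readthrough_calls.tsv`,
`peak_assignments.tsv`, `interaction_classes.tsv`, …), e.g.

```
locus_id  distance  window_start  window_end  body_mean_treatment
snrna00   1000      257234        258234      5.18
snrna01   5000      260384       265384       5.09
snrna02   15000     267534       282534       4.91
```

Each subcommand (`simulate`, `outron`, `readthrough`, `annotate-peaks`,
`de`, `smallrna`, `interaction`, `report`) also runs standalone on files
(GTF, bedGraph manifests, narrowPeak, count TSVs); see `outronscan --help`.

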