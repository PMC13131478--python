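# Methods

This note documents the models behind `outronscan`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Coordinates and data model

All internal coordinates are 0-based half-open; conversion happens only at
the GTF boundary (1-based inclusive) and is identity for BED/bedGraph.
TSS/TES are strand-aware span boundaries (a minus-strand gene's TSS is its
span end). Coverage is stored densely per (contig, strand); queries off the
stored contigs read as zero, matching the missing-data-as-zero convention
of standard metagene tooling. Strand-specific tracks follow the
reverse-stranded library convention: a gene's sense signal is read from the
track of its own strand, antisense from the opposite track over the same
interval.

## Outron quantification

The outron window is the 150 bp immediately 5′ of the TSS — reported outron
lengths in *C. elegans* range from tens of bases to ~3 kb, so a 150 bp
window captures un-trans-spliced reads while staying inside the eligibility
guard bands (no neighbour within 300 bp upstream). Usage is
`(outron_density + 0.01) / (body_density + 0.01)`; the pseudocount keeps
zero-coverage genes at usage 1 and vanishes asymptotically (usage → o/b as
coverage grows). Body density is measured over the representative
transcript's exon union rather than the genomic span, so introns do not
dilute the denominator (`body_mode="span"` restores the span reading).

Choices the source methods left open, resolved here:

* **Eligibility, upstream strand.** The 300 bp upstream-neighbour exclusion
  considers genes on *either* strand: transcription from both contaminates
  a short upstream window (the same-strand-only rule is retained separately
  as the metagene tandem-gene filter, `tss_isolated`).
* **Replicates.** Usage is computed per replicate and averaged per
  condition before the log2 ratio; the ratio of means is stabler than the
  mean of ratios at the low outron densities involved.
* **Outron read filter.** Tracks carry coverage, not reads, so the ≥5-read
  filter uses reads ≈ (window coverage sum)/read length (default 40 nt, a
  typical short-read length), pooled across replicates within a condition.
  Pooling is deliberate: at study-like densities (body λ = 5, outron
  fraction 0.1) a single replicate holds ~2 estimated outron reads for
  every gene and a per-replicate filter would discard the entire genome.
* **Upstream readthrough score.** Six 50 bp windows tile the region 150–450
  bp upstream of the TSS; the score is the OLS slope of window density
  against distance upstream. A gene is excluded when the slope is positive
  with far-upstream mean > 0.5 × body density, or when the far-upstream
  mean reaches the body density (saturating invasion). Both clauses are
  needed: a rising profile marks decaying readthrough entering the window,
  a flat-high profile marks readthrough that has not decayed at all.
* **Thresholds are inclusive** (≥), including the 0.58 log2 boundary.
  Increased and decreased calls are reported separately, and the table
  retains the unfiltered (pre-exclusion) counts alongside the
  high-confidence set.

## Termination readthrough

Profiles normalise 10 bp bins (100 bp inside the body, 500 bp downstream)
by the locus body mean, so they are invariant under global track scaling.
The distance estimator walks 100 bp bins downstream of the TES and requires
*both* absolute evidence (treatment density ≥ 0.1 × treatment body mean)
and differential evidence (treatment > 2 × control) per bin; the dual rule
prevents constitutively expressed downstream genes from being absorbed into
the readthrough window. The distance is the end of the maximal contiguous
run from the TES, capped at 15 kb. With several replicates the per-replicate
median distance is reported. Downstream-gene interference is quantified for
every gene whose span intersects the window, on the gene's own sense
strand, as a pseudocounted log2 density ratio — antisense genes therefore
read ≈ 0 unless their own strand changes. snoRNA loci run through the same
operations via the `biotypes` flag.

Promoter-upstream antisense (PROMPT-like) signal is the opposite-strand
mean over [TSS − 400, TSS); "upregulated" means log2 ratio ≥ 1 with
treatment density ≥ 0.1 — the threshold pair is a package choice (the
phenomenon has no canonical cutoff) and both knobs are exposed.

## Peak annotation

Assignment is a two-tier maximal-overlap rule: regulatory map first, then
genes. TSS/TES "features" are ±100 bp point windows (GTFs carry no such
intervals), with priority TSS > TES > exon > intron inside the assigned
gene; exon membership uses the representative transcript. Ties break on the
lexicographically smallest feature id, making assignment independent of
input order. Intronic peaks are additionally tested for an opposite-strand
TSS/TES within 300 bp (inclusive), the operon-dense-genome caveat. A
regulatory-tier assignment contributes to the bound-gene set only when the
map links the element to a gene.

## Count statistics

* **Size factors**: median-of-ratios with the reference restricted to genes
  with no zero count; factors are equivariant in the relative sense
  (scaling one sample by c multiplies its factor *relative to the others*
  by c; the geometric-mean reference absorbs c^(1/n)).
* **FDR**: Benjamini–Hochberg step-up with enforced monotonicity,
  first-principles implementation (cross-checked against statsmodels in the
  tests).
* **NB GLM**: per-gene log-link negative-binomial regression fit by IRLS
  with the design shared across genes (batched p×p solves). Dispersion is
  method-of-moments from Poisson-fit residuals, floored at 1e-8, then
  moderated toward the across-gene mean with prior weight `prior_df = 10`:
  α̃ = (df·α̂ + prior_df·ᾱ)/(df + prior_df). Wald statistics are referred
  to t(df + prior_df). The moderation is the load-bearing numerical
  choice: with three replicates the raw per-gene dispersion is so noisy
  that a normal reference is badly anti-conservative (measured type-I
  ≈ 0.13 at nominal 0.05), while an unmoderated t(n−p) reference floors
  the attainable p-values (t(4) cannot reach the BH threshold at 1,000
  genes) and zeroes the power of any sparse-signal screen. The weighted
  moderation — the standard empirical-Bayes compromise in count-based
  differential expression — restores both calibration (measured type-I
  ≈ 0.05) and power. It assumes dispersions are exchangeable across genes;
  on data with strongly mean-dependent dispersion a trended prior would be
  preferable (not implemented). No fold-change shrinkage and no independent
  filtering are applied.
* **Interaction model**: design [1, genotype, treatment, genotype ×
  treatment] with wt/control reference levels, so `beta_treatment` is the
  wild-type knockdown effect and `beta_interaction` the mutant-vs-wt
  difference of that effect. Classification among significantly
  wt-downregulated candidates (β_t ≤ −0.5, padj < 0.05): *reversed* when
  the interaction is significant (padj < 0.05, β_i ≥ 0.5) and the combined
  mutant effect β_t + β_i is positive; *attenuated* when significant but
  the combined effect stays ≤ 0; otherwise *unchanged*. Whether
  "attenuated" requires interaction significance is genuinely ambiguous in
  the source analyses; requiring it keeps the three classes mutually
  exclusive and FDR-controlled.
* **22G classification**: a read is 22G when 21–23 nt, 5′ G, and antisense
  to a protein-coding gene; sense miRNA-locus overlap takes priority. The
  strict 5′-G rule (rather than a bias) makes the classifier deterministic;
  bounds and the required nucleotide are configurable. Quadrant targets
  require 22G up and mRNA down, both at padj < 0.05 — only the directions
  are canonical, the significance pairing is a package default.

## Synthetic-data generator

One toy chromosome (a few hundred kb at defaults) holds well-separated
single- and two-transcript protein-coding genes, an snRNA cluster with
readthrough corridors, regulatory elements, and PROMPT-like antisense
windows. Coverage is per-base Poisson: replicate variability enters through
independent replicate draws, while the count matrices use NB dispersion
where overdispersion matters. Defaults are the conditions exercised
throughout the tests: body λ = 5, outron background fraction 0.1, retained
genes shifted +1 log2 in treatment, 3 replicates; counts at mean 100,
dispersion 0.05, n = 3 per group.

Generator features worth knowing:

* **Readthrough decay** is exponential (τ = 2 kb) from the snRNA body level
  but floored at 0.2 × λ_body inside the corridor and hard-truncated at
  the planted extent. A pure exponential would cross the estimator's 0.1
  relative threshold at τ·ln10 ≈ 4.6 kb regardless of the planted extent,
  making long extents undetectable by construction; the floor makes the
  truncation point the unambiguous target of the estimator. Corridor
  ("operon-like") downstream genes are basally quiet (0.05 × λ_body) so
  coverage gains there are attributable to invading readthrough, matching
  the interference interpretation.
* **Planted effect sizes** for the count modules were fixed by an a-priori
  power analysis against the package's own test statistic: wild-type
  knockdown β_t = −2.5 log2 for planted genes; interaction +3.0 (reversed,
  combined mutant effect +0.5) or +2.0 (attenuated, combined −0.5); 22G
  targets +3.0 log2 with mRNA −2.0. These sit at 4–5 SE of the relevant
  contrasts at three replicates per group — strong but realistic effects
  for silencing screens — so recovery failures indicate implementation
  errors rather than power limits.
* **Determinism**: every output is a pure function of the seed (independent
  numpy `SeedSequence` streams per stage/condition/replicate); the pipeline
  embeds a config hash in every table header and reruns are byte-identical.

What the generator does **not** emulate — hence what passing tests do not
show about real data: genomic sequence content (no mappability or GC
structure), overlapping/nested transcription units, operonic SL2 biology,
fragment-level autocorrelation of read coverage (per-base Poisson is
smoother than real coverage), mean-dependent dispersion trends, and
unbalanced designs.

## Problem sizes

The test suite and the acceptance script run the full stated conditions:
200-gene outron panels with 3 replicates per condition, 1–15 kb readthrough
corridors, 1,000-gene count and small-RNA matrices, 2,000-gene null
calibrations, and 1,000 peaks × 200 elements for the annotation oracle.
The complete suite and the acceptance script each finish in well under a
minute on a single CPU.

## Known limitations

* Outron read counts are coverage-derived approximations, not alignments;
  genes with highly structured coverage can mis-estimate the read filter.
* The distance estimator reports bin-end distances (100 bp granularity) and
  saturates at `max_extent`; it does not model multi-modal readthrough.
* The NB analog is not a DESeq2 reimplementation: no dispersion trend, no
  LFC shrinkage, no outlier refitting; results on real data will differ in
  the tails.
* The 22G rule is deliberately strict; reads with a non-G 5′ nucleotide are
  never 22G regardless of context.
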