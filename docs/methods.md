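# Methods

This note documents the models, conventions and design choices behind
`ltrdyn`, in the order the pipeline runs them.

## Coordinates and formats

Internal coordinates are 0-based half-open everywhere. GFF3 files are
1-based closed on disk and converted at the file boundary; BED and the
methylation TSV positions follow their native conventions (BED half-open,
methylation positions 1-based on disk). TE GFF3 records carry `Family`,
`Superfamily`, `Status` (intact / truncated / solo_LTR), LTR sub-intervals
(`LTR5`, `LTR3`) and the flanking target-site-duplication strings (`TSD5`,
`TSD3`) as attributes.

## Insertion dating

LTR pairs are aligned with a global pairwise aligner (Biopython's
`PairwiseAligner`) under affine gap penalties (match +1, mismatch −1, gap
open −5, gap extend −1). Two sequences need only a pairwise alignment, so no
multiple-alignment program is involved; the first optimal alignment is taken,
which is deterministic for fixed inputs. Columns containing a gap or an N
are excluded; transitions are A↔G and C↔T, all other mismatches
transversions. The Kimura two-parameter distance
`k = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` corrects for multiple hits; when an
argument of a logarithm is non-positive the pair is *saturated* and the
estimate is reported as NaN with a flag rather than clamped — silent
clamping would pile saturated copies onto an arbitrary age and bias the
distribution. Ages are `T = k/(2r)` in years with `r = 1.3 × 10⁻⁸`
substitutions/site/year by default; summaries report the median, a
histogram, and the fraction younger than a configurable threshold (default
1 Myr). Saturated estimates are excluded from all fractions but counted.

Newly originated copies are those with byte-identical LTRs *and* identical
5-bp TSDs; a 4-bp or mutated TSD disqualifies a copy even when its LTRs are
identical. Copies young enough to have escaped any substitution are
indistinguishable from true age-0 insertions, so the flag is a lower bound
on recency, not an exact age-0 detector.

## Genomic context

Coding bases are the union of CDS features; intron bases are exon gaps not
overlapping any CDS; everything else is intergenic — the three categories
partition the genome exactly. A copy spanning a boundary is *counted* once
with priority coding > intron > intergenic (the most consequential overlap
wins), while the DNA-occupancy *fractions* use per-base overlap so they
remain a true coverage measure; the two statistics answer different
questions and deliberately use different rules. Elements/Mb uses
category-specific DNA as the denominator (per-genome-Mb is emitted as a
secondary column, since either reading of a per-Mb table is defensible).

Gene density is the CDS fraction of 100-kb windows tiled at 50-kb steps from
position 0 of each scaffold; the final window is truncated at the scaffold
end and its density computed over its actual length, and a scaffold shorter
than the step yields a single whole-scaffold window. A copy inherits the
density of the overlapping window with the largest overlap (leftmost on
ties). Gene-poor means density < 0.05. A minimum-scaffold-length filter is
exposed and defaults to 0 (synthetic scaffolds are uniform; on real
assemblies short scaffolds can be excluded as in window-based practice).

The S:I ratio is solo-LTR count over intact count per superfamily, reported
at two decimals; with no intact copies the ratio is flagged undefined rather
than forced to a number.

## Epigenome quantification

Methylation context is called from the reference: for a cytosine, the next
two bases 3′ on its strand give CG, CHG or CHH (H ∈ {A, C, T}); minus-strand
calls use the reverse complement, and truncated or N-containing contexts are
skipped. Element levels pool raw counts — `Σ#C / (Σ#C + Σ#T)` over
qualifying sites — rather than averaging per-site ratios; pooling weights
sites by coverage, which is the natural estimator for binomial counts (the
mean-of-ratios variant is emitted as a secondary column). "Covered by more
than three reads" is implemented strictly as coverage ≥ 4. An element with
no qualifying site in a context has a missing level, never zero.

siRNA density is `Σ (1/n_hits) / (length/1000)` over alignments whose 5′
start lies inside the element; judging membership by the start position
avoids double-counting reads spanning element edges, and the `1/n_hits`
weight makes the total contributed weight of every read exactly one. The
24-nt filter is applied for repression analyses (the de novo silencing
signal is carried by 24-nt siRNAs) but can be disabled to pool all putative
siRNAs. Structural-RNA removal is assumed done upstream. The repression
contrast splits elements at resident gene density < 0.05 and compares groups
with a two-sided Mann–Whitney test.

## Expression screen

TE expression is reads per kilobase of element; gene expression is RPKM.
The expressed filter requires raw counts strictly above 5 in *both*
replicates of at least one salt condition, per tissue; raw counts are used
because the threshold is a detection rule, not a quantification.

Differential expression is a negative-binomial Wald test written out
explicitly: median-of-ratios size factors (total-count fallback when every
feature row contains a zero), per-feature method-of-moments dispersion
pooled across the two groups and floored at 10⁻⁸, a delta-method standard
error on the log2 ratio of normalized group means (pseudocount 0.5 when a
mean is zero, to keep the fold change finite while preserving sign), BH
adjustment, and significance at FDR < 0.05 with |log2FC| ≥ 1. With two
replicates per group the dispersion estimate is noisy and the test is
approximate; the type-I calibration on a 2000-feature null is part of the
test suite.

TE–gene pairs are formed when the nearest-edge gap is ≤ 3 kb, or the TE lies
fully inside an intron (relation `intron`, distance 0, taking priority over
the distance rule); the relation labels the TE's position relative to the
gene, strand-aware. Enrichment of mis-expressed genes among TE-adjacent
genes uses the two-sided Fisher exact test.

Expression correlation uses Pearson's r. The primary mode correlates
per-condition mean expression (n = 3 salt conditions); because a t test on
one degree of freedom has essentially no power (r = 0.99 gives p ≈ 0.09),
a replicate-level mode (n = 6) is provided and is the mode used for all
power-dependent calibration checks. Zero-variance profiles are reported as
untestable, and p-values are BH-adjusted per tissue.

miRNA-sponge candidates require (i) a miRNA with predicted sites on both a
TE and a transcript (target prediction and expectation-score filtering are
upstream inputs), (ii) a same-strand local match ≥ 20 nt at ≥ 90% identity
whose TE-side span covers the TE's binding site — antisense matches never
qualify, as sequences are compared exactly as given — and (iii) both
features passing the expression filters. The 20-nt/90% thresholds are
package defaults, exposed in the API, as the sponge-competition literature
states the criteria qualitatively. The local-match search takes the single
best local alignment; a weaker secondary match covering the site would be
missed, which is acceptable for the screen's candidate-nomination role.

## Synthetic data generator

The generator produces data *from the same models the analyses assume*, so
every stage closes a recovery loop against recorded truth. It emulates the
study conditions, not any particular genome.

* **Substitution process.** Each LTR of an intact copy evolves independently
  from a common ancestral sequence: per site, a Poisson number of events
  with mean `rate × age` per branch; an event is a transition with
  probability κ/(κ+2) (default κ = 2), otherwise one of the two
  transversions. Expected pairwise divergence is exactly `2 r T`, making the
  K2P dating model the generator's inverse. Indels are not simulated.
* **Genome layout.** Chromosomes (default two of 1 Mb) are designated
  gene-poor (no genes; every window < 0.05) or gene-dense (genes of
  two 1-kb exons around a 3.1-kb intron every 12 kb; every window ≥ 0.15)
  according to the configured gradient. The two-block design makes the
  gene-poor threshold deterministic — no window falls in the ambiguous band.
* **TE placement.** Copies are placed without overlap from interval pools:
  intergenic gaps, intron interiors (the 3.1-kb intron fits a whole 3-kb
  intact element), reserved CDS-overlap slots, and the gene-poor
  chromosomes, with per-family gene-poor preference. Requested placements
  that exceed capacity overflow to the other compartment and the recorded
  truth always reflects the realized placement; outright infeasibility is an
  error. Intact copies get 5-bp TSDs, identical for age-0 copies and
  substitution-mutated in proportion to age otherwise.
* **Methylome.** Per cytosine inside elements: Poisson coverage (default
  mean 20), binomial methylated counts with per-context probabilities that
  depend on the element's compartment — CHH 0.10 (gene-poor) vs 0.45,
  CG 0.60/0.90, CHG 0.30/0.70 — matching the direction and rough magnitude
  of heterochromatic repression contrasts in plants.
* **siRNA.** 24-nt reads at 4 (gene-poor) vs 8 (gene-rich) reads/kb; a
  configurable fraction multimaps to 2–3 same-family copies.
* **Counts.** Negative-binomial with lognormal per-feature base means
  (median 100) and dispersion 0.01 (replicate CV ≈ 10%, appropriate for the
  high-count features the screen retains — the planted-pair recovery
  calibration presumes exact collinearity of condition means, which only
  low replicate noise can transmit). TEs get a two-fold root boost. Planted
  TE–gene pairs share a condition-mean profile: the TE and positive-sign
  genes scale as 2^(lfc·step) across conditions, negative-sign genes follow
  the affine reflection (max+min−profile), which is exactly anti-collinear —
  a log-scale reflection would cap the attainable raw-scale correlation near
  −0.7 and could never realize a planted r of −1. Library sizes are left
  equal by default so normalization cannot mask planted effects.

What the generator does *not* emulate: read-level sequencing error,
bisulfite conversion failure, indels and nested insertions, mapping
ambiguity beyond the multimap count, batch effects, and genuine biological
dispersion heterogeneity. Passing recovery tests therefore demonstrates the
estimators invert their assumed models, not that those models capture every
property of real data.

## Problem sizes in tests

The bundled suites run the dating round-trip at 200 replicate pairs per age
(1-kb LTRs, ages 0.5–5 Myr), oracle comparisons on 20 random 30-kb
annotations, the methylation recovery on 120 elements at coverage 20, the
DE null on 2000 features, and the correlation calibration on 50 planted plus
500 null pairs — sizes at which every Monte-Carlo criterion is stable across
seeds while the whole suite stays fast.

## Known limitations

* The NB Wald test is a deliberately explicit reimplementation, not a
  shrinkage estimator; with two replicates it is less powerful and less
  stable than moderated methods.
* Pearson correlation across three conditions (primary mode) has almost no
  inferential power; it is reported for comparability, with the
  replicate-level mode carrying the statistics.
* The sponge screen inspects only the best local match per feature pair.
* Dating assumes substitutions only; gene conversion between LTRs,
  insertions within LTRs, or non-neutral LTR evolution bias ages downward
  or upward without detection.
* One printed-input discrepancy is carried as-is: the source tables report
  49/76 intact Copia/Gypsy for the second species where the text says
  51/74; the accounting reproduces whichever annotation it is given, and
  the worked totals use the text values (51 + 74 = 125).
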