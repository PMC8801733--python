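# ltrdyn

Evolutionary dynamics and regulatory impact of LTR retrotransposons, as a
tested, reusable pipeline. The package implements the analysis workflow used
to study retrotransposon bursts in mangrove genomes (*Sonneratia alba* and
relatives): insertion-age dating from LTR-pair divergence, genomic-context
accounting, quantification of epigenetic repression, and a salt-stress
TE–gene co-expression screen. A synthetic-data generator with a recorded
ground truth makes every stage verifiable without any external downloads.

It is aimed at researchers in plant genome evolution who have a genome
assembly, TE and gene annotations, bisulfite and small-RNA data, and a
stress RNA-seq design, and who want the standard LTR-retrotransposon
analyses in one auditable toolchain.

## What it computes

**Insertion dating.** The two long terminal repeats of a retrotransposon are
identical at insertion and diverge neutrally afterwards. For each intact
copy the LTR pair is globally aligned, transition (P) and transversion (Q)
proportions are counted over ungapped columns, corrected with Kimura's
two-parameter distance

```
k = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
```

and converted to an age `T = k / (2r)` with `r = 1.3e-8`
substitutions/site/year by default. Saturated pairs are flagged, never
clamped. Copies with identical LTRs and perfect 5-bp target-site
duplications are flagged as newly originated. Age distributions are
summarized (median, young fraction below 1 Myr) and compared with
Mann–Whitney U tests.

**Genomic context.** Each insertion is classified as coding, intronic or
intergenic (priority coding > intron > intergenic); per-superfamily density
tables report elements/Mb of category DNA and the fraction of category DNA
occupied. Gene density is the coding fraction of 100-kb windows at 50-kb
steps; density < 0.05 defines gene-poor (heterochromatin-like) regions.
Solo-LTR : intact-element (S:I) ratios index element removal by unequal
recombination.

**Epigenetic repression.** Per-element methylation is the pooled proportion
of methylated cytosine calls `#C / (#C + #T)` per context (CG, CHG, CHH),
over sites covered by more than three reads. siRNA density is weighted reads
per kilobase per element, multimappers down-weighted by `1/n_hits`.
Gene-poor versus gene-rich residents are contrasted with Mann–Whitney tests.

**Expression screen.** TE expression as reads/kb, genes as RPKM; features
are expressed when one salt condition has > 5 reads in both replicates.
Differential expression uses a negative-binomial Wald test (median-of-ratios
normalization, method-of-moments dispersion, BH-FDR; significant at
FDR < 0.05 and ≥ 2-fold). Genes within 3 kb of a TE (or hosting one in an
intron) are paired with it, tested for enrichment of mis-expression (Fisher
exact) and screened for Pearson correlation across salt conditions.
miRNA-sponge candidates require a shared miRNA target plus a sense-strand
sequence match covering the TE's binding site.

## Worked example

Generate a synthetic dataset and run the whole pipeline:

```
$ ltrdyn run --outdir fullrun --seed 2
report written to fullrun (config dbfb2372eb37368d)
```

or stage by stage:

```
$ ltrdyn simulate --seed 4 --outdir sim
$ ltrdyn date-ltrs --genome sim/genome.fa --tes sim/tes.gff3 --out dates.tsv
80 dated copies, median 0.86 Myr, young(<1.0 Myr) fraction 0.525, 0 saturated
$ ltrdyn context --genome sim/genome.fa --genes sim/genes.gff3 \
      --tes sim/tes.gff3 --out-prefix ctx
$ ltrdyn epigenome --meth sim/methylation.tsv --sirna sim/sirna.bed \
      --tes sim/tes.gff3 --density ctx.copy_context.tsv --out epi.tsv
CHH_level: gene-poor median 0.100 vs other 0.451 (p=9.43e-14)
sirna_density: gene-poor median 4.444 vs other 7.194 (p=5.10e-12)
```

The dating line says 80 intact copies were dated, half of them younger than
1 Myr, none saturated. The epigenome lines recover the repression contrast
planted by the simulator: elements resident in gene-poor windows carry CHH
methylation near 0.10 versus 0.45 elsewhere, and about half the 24-nt siRNA
density — the signature of relaxed RNA-directed silencing in
heterochromatin-like regions. Per-copy tables (`dates.tsv`, `epi.tsv`,
`ctx.*.tsv`) carry every number behind these summaries.

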