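# ldblock-enrich

Are the genomic regions tagged by GWAS top hits unusually rich in
non-coding annotation?  `ldblock-enrich` answers this for four element
classes — lncRNA genes, miRNA precursors, circRNAs and super-enhancers
(SEs) — by working at the level of **haplotype blocks** rather than single
SNPs: an associated SNP tags its whole LD block, so the block, not the
point position, is the right unit for overlap counting.

The package is aimed at statistical geneticists and regulatory-genomics
analysts who have (i) genome-wide genotypes from a reference cohort (or a
pre-computed block map), (ii) a list of disease-associated SNPs, and
(iii) annotation tracks in standard formats (GENCODE GTF, miRBase GFF3,
circBase-style tab text, BED).

## Method

1. **Haplotype blocks.** Pairwise LD is estimated from unphased diploid
   genotypes: two-locus haplotype frequencies by EM over the
   double-heterozygote ambiguity, then Lewontin's D′ = |D|/D_max with a 90%
   confidence interval obtained by profiling the multinomial genotype
   likelihood over a D′ grid.  Blocks follow the Gabriel
   confidence-interval criteria with the Haploview default thresholds
   (strong LD: CI lower ≥ 0.70 and upper ≥ 0.98; strong recombination:
   upper < 0.90; ≥ 95% informative pairs in strong LD; 200-kb window).
2. **Mapping.** Each disease SNP is assigned to the block containing its
   position (block borders are the outermost member SNPs, both inclusive);
   duplicate blocks collapse to one.
3. **Overlap.** An annotation element counts if it shares ≥ 1 bp with any
   block (partial or total overlap), once per element, after redundancy
   filtering on (class, id, chrom, start, end).
4. **Enrichment.** The null is a matched bootstrap: random SNPs drawn from
   the array manifest — stratified to mirror the disease list's intronic
   fraction, avoiding the HLA region and chromosome X — are mapped to
   blocks and their element counts recorded.  Matching is on SNP count
   (Random set I) or on total block territory (Random set II).  With *r*
   the number of the *n* iterations whose count meets or exceeds the
   observed one, the empirical p-value is the Davison–Hinkley estimator

   *p* = (*r* + 1) / (*n* + 1),

   reported per class, unadjusted.

A synthetic-data module generates every input with known ground truth
(haplotype-pool genotypes, manifests with controlled intronic fractions,
Poisson annotation tracks with planted enrichment), so the entire pipeline
is testable offline.

## Worked example

```python
from ldblock_enrich import EnrichmentModel, make_paper_shaped_fixture

bundle = make_paper_shaped_fixture(seed=11)   # 97 disease SNPs, 73 blocks,
                                              # circRNA & SE planted at 3x
model = EnrichmentModel(bundle.disease_snps,
                        manifest=bundle.manifest,
                        blocks=bundle.blocks,
                        tracks=bundle.tracks,
                        constraints=bundle.constraints)
res = model.fit(n_iterations=200, seed=5)
print(res.summary())
```

prints

```
Enrichment bootstrap: 200 iterations, seed 5
           n_blocks block_kb dna_mb lncRNA circRNA  miRNA     SE
observed         73     56.2    4.1     37     720      1     28
null_mean      66.3     66.3    4.4   47.8   288.3    4.7   10.3
null_sd         4.3      2.6    0.3    7.4    30.6    2.2    3.6
exceed_pct        -        -      -   93.5     0.0   99.5    0.0
p_value           -        -      -  0.935   0.005  0.995  0.005
```

Reading the table: the 73 disease blocks cover 4.1 Mb and contain 720
circRNAs versus a null mean of 288.3 ± 30.6; no iteration reached the
observed count (exceedance 0%), so the circRNA p-value is the estimator's
floor at 200 iterations, (0+1)/(200+1) ≈ 0.005.  The same holds for the
super-enhancers — the two classes planted at 3× density — while lncRNA and
miRNA, planted at background density, stay far from significance.
`res.plot_null("circRNA")` draws the null histogram with the observed count
marked.

The same analysis runs from the shell:

```sh
ldblock-enrich simulate --out demo --seed 11
ldblock-enrich run --config demo/config.yaml
```

and `ldblock-enrich blocks / overlap / test / compare` expose the
individual stages (blocks from a VCF or dosage matrix, overlap counting,
the bootstrap test, and multi-disease comparison over a shared null).

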