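# Methods

## Scope and model

The package tests whether the LD blocks harboring a set of
disease-associated SNPs are enriched in non-coding annotation relative to
blocks tagged by random, constraint-matched SNPs.  It assumes:

* unphased diploid genotypes with biallelic markers; dosages in {0, 1, 2};
* autosomes only (chromosome X is excluded throughout, as is a
  configurable HLA interval, whose extreme LD would otherwise dominate any
  block-based statistic);
* annotation elements are fixed genomic intervals; an element is "in" a
  block when it shares at least one base pair with it, partially or
  totally;
* the null hypothesis is that disease SNPs behave like random array SNPs
  with the same intronic/extragenic composition.

## Pairwise LD

Two-locus haplotype frequencies are the MLE under random mating, obtained
by EM over the double-heterozygote phase ambiguity.  Samples missing at
either locus are excluded pairwise (the behavior of the standard desktop
LD software).  Convergence: maximum frequency change < 1e-9 or 1,000
iterations; initialization at linkage equilibrium.  The EM update
preserves the observed allele frequencies at both loci, so the fitted
marginals equal the sample MLEs — the property the grid-search oracle in
the test suite relies on.

D′ = |D|/D_max with D = p_AB − p_A·p_B and
D_max = min(p_A·p_b, p_a·p_B) for D > 0, min(p_A·p_B, p_a·p_b) for D < 0;
D′ = 0 when D = 0.  D′ is invariant to allele relabeling and to locus
order (property-tested).

The 90% confidence interval on |D′| profiles the multinomial genotype
likelihood over D′ ∈ {0, 0.01, …, 1} with the marginals held at their MLEs
and the sign of D taken from the EM estimate.  The profile is normalized
to unit mass and 5% is trimmed from each tail: the lower bound is the
smallest grid value whose cumulative mass reaches 0.05, the upper bound
the largest whose upper-tail mass (including the point) reaches 0.05.
Likelihood cells with zero observed counts contribute nothing, which keeps
the profile finite at the D′ = 1 boundary where some haplotype classes
vanish.  Grid step (0.01) and tail mass (0.05) are exposed as parameters.

## Block calling

Gabriel-style confidence-interval calling with the defaults of the
software the procedure is named after:

| parameter           | default | meaning                                       |
|---------------------|---------|-----------------------------------------------|
| `max_window_bp`     | 200,000 | maximum pair distance and block span (bp)     |
| `strong_ld_ci_low`  | 0.70    | CI lower bound for a "strong LD" pair         |
| `strong_ld_ci_high` | 0.98    | CI upper bound for a "strong LD" pair         |
| `recomb_ci_high`    | 0.90    | CI upper bound below which a pair shows recombination |
| `inform_frac`       | 0.95    | required strong-LD share of classified pairs  |
| `min_maf`           | 0.05    | minimum minor-allele frequency for informativeness |

A candidate block is a SNP run [i..j] whose endpoint pair is in strong LD
and whose classified pairs are ≥ 95% strong LD; candidates are accepted
greedily by decreasing physical span (ties by position), blocks never
share SNPs, and block membership is the full contiguous SNP run.  Low-MAF
SNPs do not form pairs but are carried as members when interior to an
accepted span.  Block intervals store `start = 5′-member position − 1` and
`end = 3′-member position` (0-based half-open), so both border SNPs are
inside the block under half-open containment; block length is `end −
start`.  The module is fully deterministic.

The per-chromosome classification is quadratic in SNPs-per-window; that is
adequate for the cohort scales the package targets and for the synthetic
genomes in the test suite, but a banded/streaming implementation would be
needed for a biobank-scale manifest in one pass.

## Overlap counting

Interval intersection uses an interval tree (O((n+m) log n)); an
independent quadratic all-pairs scan in the test suite guards its
correctness on random instances.  Redundancy filtering keys on
(class, id, chrom, start, end): the same element reported by two source
studies counts once; distinct ids with identical coordinates stay
distinct.  A super-enhancer touching two disjoint blocks counts once.  The
≥ 1 bp overlap threshold is the most permissive reading of "partial or
total overlap" and is exposed (`min_overlap_bp`) for sensitivity analysis.

## The bootstrap null and its p-value

Random SNPs are drawn uniformly without replacement, stratified:
`round(fraction · k)` from the intronic stratum, the rest from the
extragenic stratum; manifest SNPs categorized neither way are not eligible
(the matched draw mirrors the two-list construction used with array
manifests).  SNPs on excluded chromosomes or inside excluded regions
(default: chr6:25,000,000–35,000,000, an hg19-convention MHC interval) are
never drawn.  The intronic fraction defaults to the fraction observed in
the supplied disease list.

* **Mode I** (`match_snp_count`): draw `n_snps` per iteration, map to
  blocks, deduplicate, count.
* **Mode II** (`match_total_length`): draw SNPs one at a time from a
  stratified stream, accumulating unique block territory, and stop at the
  first SNP whose block pushes the total past `target − tolerance`
  (tolerance defaults to 5% of the target).  Because random SNPs land in
  blocks with probability proportional to block length, mode II corrects
  the length bias mode I inherits.

Draws are independent across iterations (bootstrap semantics): iteration
`i` uses the deterministic RNG substream `(seed, spawn_key=(i,))`, so a
run is bit-reproducible from its seed and independent of execution order.

Exceedance uses ≥ (ties count against enrichment);
p = (r + 1)/(n + 1), bounded below by 1/(n + 1); four classes are reported
unadjusted, with the null mean and SD per class.  The model also records
per-iteration block counts and territory so the summary table can report
the null's block statistics alongside the element counts.

`EnrichmentModel.calibrate()` is a built-in diagnostic: it draws
pseudo-observed sets from the null itself and returns their p-values,
which should be (sub)uniform — "sub" because integer counts tie with
positive probability and ties are scored conservatively.

## Synthetic data: what it does and does not emulate

The genotype generator plants blocks as haplotype pools: each sample's two
haplotypes within a block are drawn from a small shared pool (size 2 by
default, giving within-block D′ = 1 up to sampling noise); between blocks
loci segregate independently.  This gives exact, known block boundaries —
the point of the generator — at the cost of realism: no recombination
gradient, no allele-frequency spectrum, no population structure, no
genealogy.  Passing the block-recovery suite therefore shows the caller
implements the CI criteria correctly on clean block structure, not that it
reproduces any particular cohort's block map.

Tracks are homogeneous Poisson processes (background density per Mb;
density × factor inside designated disease blocks, by superposition for
factor > 1 and thinning for factor < 1).  Real annotation is clustered in
genes and correlated across classes; the Poisson model instead matches
exactly the uniform-placement assumption implicit in the random-SNP null,
which is what makes the calibration and power suites interpretable.

The bundled study-shaped fixture uses eight 30-Mb chromosomes, a block map
with 10–100-kb blocks separated by 5–35-kb gaps (≈ 73% block coverage),
97 disease SNPs of which 73 land in distinct blocks and 24 in none, a
20,000-SNP manifest with half the SNPs intronic, 94 random SNPs per null
iteration, and tracks at 8 (lncRNA), 60 (circRNA), 1 (miRNA) and 2 (SE)
elements per Mb with circRNA and SE planted at 3×.  These sizes keep every
statistical check sharp (hundreds of blocks, tens-of-thousands of SNPs)
while a full fit runs in seconds; the calibration suite uses a smaller
four-chromosome variant with 30-SNP draws, 200 iterations and 500
replicates for the same reason.

## Design decisions taken where the procedure was open

* **miRNA coordinates** are precursor (hairpin) intervals, the primary
  feature of the miRBase genomic GFF3; mature products are ignored.
* **circbase_tab dialect** is fixed as
  `chrom  start(0-based)  end  id  gene  [source]` with an optional
  header; other circBase exports should be reshaped to it (an `awk`
  one-liner: `awk -v OFS='\t' '{print $1,$2,$3,$4,$5}'` over the relevant
  columns).
* **CNV exclusion** in manifests: rows whose optional type column flags a
  copy-number probe, or whose id starts with `CN_` (the Affymetrix 6.0
  CNV-probe prefix), are dropped.
* **Multiple disease SNPs in one block** collapse to one block with a
  warning rather than an error: the strict one-SNP-per-block outcome is a
  property of a particular input, not a contract the pipeline can impose.
* **Internal coordinates** are 0-based half-open everywhere; GTF/GFF are
  shifted at the I/O boundary, BED and circbase_tab pass through; 1-based
  SNP positions convert via `pos − 1`.  Chromosome labels drop the `chr`
  prefix internally.

## Known limitations

* Exact parity with any particular Plink/Haploview build is a tuning
  exercise (all thresholds are exposed) — released implementations differ
  in small CI-grid and tie-handling details.
* Index SNPs are mapped as points; no r²-based proxy expansion.
* The null randomizes SNPs, not the annotation (no circular-permutation /
  genomic-rotation null), so correlation between annotation classes is
  not modeled.
* P-values are reported per class without multiple-testing correction,
  matching the report-table convention; users comparing many classes or
  diseases should correct downstream.
* Liftover between assemblies is out of scope; all inputs must share one
  assembly.
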