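# Methods

This note records the models the package implements, the synthetic panel
they are exercised on, and the numerical and design choices that were
genuinely open.

## Association models

**GLM.** Per variant, ordinary least squares of the trait on an intercept,
k principal components (default k = 3) of the column-standardised dosage
matrix, and the variant dosage; two-sided t test on the dosage coefficient
with n − k − 2 degrees of freedom. The per-variant fits are computed by
Frisch–Waugh residualisation against the QR factor of the covariate block,
which is algebraically identical to the full normal equations (verified to
1e-8 against an independent oracle) and vectorises over variants.

**MLM / CMLM.** y = Xβ + x·b + u + e with Var(u) = σ²g·K. K is VanRaden
method-1 kinship, ZZ′/Σ2p(1−p) on 2p-centred dosages — the kinship formula
is not pinned by the protocol this follows (a GAPIT default), so the choice
is fixed and documented here. The variance ratio h = σ²g/(σ²g+σ²e) is
estimated once on the null model by REML on the eigen-rotated data (bounded
scalar minimisation, xatol 1e-6) and reused for every variant (P3D); full
per-variant REML would change third-decimal p-values at desk scale and is
out of scope. Optional compression clusters accessions by average-linkage
hierarchical clustering on max(K)−K and replaces K with group-mean blocks;
`compression_level=0` picks the group count from {n, n/2, n/4} by null
REML likelihood, `None`/n disables it. Negative eigenvalues of K are
clipped at zero. Missing dosages are mean-imputed per variant for
association only; monomorphic variants are flagged untested (NaN), never
fitted.

**Genomic inflation** is the median observed 1-df χ² over its expected
median — used only as a diagnostic.

## Conditional permutation threshold

Y is split into P (fitted values of a joint least-squares regression of Y
on the PCs plus intercept) and G = Y − P. Reading the protocol's "average
effect of each PC … through regression" as a joint fit is a choice; the
per-PC marginal alternative is provided (`decompose_marginal`) and
coincides with the joint fit when the PC columns are orthogonal. Each
permutation reconstructs P + shuffle(G) (Fisher–Yates through
`numpy.random.Generator.permutation`, single seed) and rescans with the
same model, covariates and — for the mixed model — the same whitening
transform. The threshold is the `percentile` (default 95) of the
per-permutation genome-wide maxima, taken as the order statistic
(`method="higher"`), i.e. the 50th-largest of 1,000 maxima. The pooled
alternative (percentile of all permuted statistics) is implemented behind
`convention="pooled"`; maxima is the default because a single study-wide
cutoff is a maximum-statistic quantity.

**Pre-filtering caveat.** Restricting the permuted rescans to variants with
*observed* −log₁₀(p) ≥ 2 is an efficiency device for panels with millions
of variants. At desk scale (thousands of variants) the pre-filtered set is
selected by the observed scan, which breaks the exchangeability between
the observed and permuted maxima and biases the threshold low; the
pipeline therefore defaults to a full rescan (`prefilter=0`) and exposes
`prefilter=2.0` for fidelity to the published shortcut. With the full
rescan, the family-wise error of the procedure on null structured panels
is 0.03 (200 datasets × 200 permutations), within sampling error of the
nominal 0.05. A trait exactly explained by structure leaves G equal to
zero up to float noise; G is snapped to exact zeros so all permutations
reconstruct the identical phenotype.

## QTL calling and linkage intersection

Significant variants are chained per chromosome while adjacent gaps are
≤ 170 kb (single-linkage on gaps, not a sliding window); chains with ≥ 3
members become QTLs spanning min..max member positions with no flanking
extension. The ≥ 3-SNP rule is enforced at the type level. Overlap
classification between QTL lists uses raw span intersection ("identical"),
intersection within a slack ("nearby", default slack 0), or "unique" with
the distance to the closest same-chromosome interval — the
identical/near distinction has no numeric definition in the source
protocol, so the distance is reported and interpretation left to the user.
Linkage intersection keeps significant variants inside GWAS×linkage
overlaps whose cross parents carry different, non-missing genotypes;
a missing parent call drops the variant with a log entry.

## Candidate screen

Pools are the 20 highest- and 20 lowest-trait accessions within the
PC1-typical region of a subpopulation; absolute PC1 cutoffs (the published
−400/300 are data-specific) are accepted, the default excludes the middle
20% of PC1 by quantile. Ties on the trait break by accession id. The
pooled χ² is the hand Pearson formula N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) on
allele copies with missing genotypes excluded, 1 df, no continuity
correction; α = 0.05 without multiple-testing correction (none is used in
the source protocol), with a Bonferroni option. `direction_ok` requires
the trait-increasing allele (GWAS β sign) to be more frequent in the
high pool.

Variant effects: zone by strand-aware coordinates (ORF = inside a CDS
segment; promoter = 2000 bp upstream of the strand-aware TSS, truncated at
chromosome edges; everything else, including introns, is reported
intergenic). CDS SNPs are translated codon-wise with the standard code;
"large-effect" is defined here (the protocol leaves it undefined) as stop
gain/loss, start loss, frameshift (InDel length ≢ 0 mod 3), or a
splice-boundary hit within 2 bp of an internal CDS junction — configurable.
Expression: ratio of mean robust-root to mean control-root RPKM with a
pseudo-count ε = 0.1 on both means (zero handling is unspecified
upstream); differential iff ratio > 1.3 or < 0.77; root-specific iff mean
root RPKM ≥ 1 and mean shoot RPKM < 1.

A gene is a candidate iff it passes pooled-χ² at some member variant, its
QTL either lacks linkage coverage (neutral) or some member variant survives
the parental-difference filter, it carries a non-synonymous or large-effect
variant, and it shows differential or root-specific expression. Genes
meeting everything but the expression clause are *deferred* and promoted
iff their haplotype–phenotype test is significant in any scope — this is
the protocol's third expression pattern ("no differential expression but
significant phenotypic differences between alleles"), whose boolean
combination is narrative upstream and stated explicitly here. Screening is
monotone; a stage-count ledger is emitted.

## Haplotype statistics

Gene haplotypes are read directly from homozygous dosages at the defining
variants (non-synonymous/large-effect ORF variants plus promoter
variants); heterozygous or missing calls exclude the accession, counted.
Major haplotypes have frequency ≥ 5% (the 2–5 major haplotypes reported
upstream imply no cutoff; 5% is configurable). Two major classes are
compared by a Welch t-test (the upstream t-test variant is unspecified;
unequal variances is the safer default). Three or more use one-way ANOVA
protected Duncan: letter groups are assigned only when the global F test
is significant at α, with critical ranges
q_{1−(1−α)^(p−1)}(p, df)·√(MSE/ñ) from `scipy.stats.studentized_range`,
ñ the harmonic mean of the end-group sizes, and maximal non-significant
runs lettered greedily. Letter consistency is re-checked pairwise in the
tests.

## Diversity and trees

SNP-table diversity with no invariant-site data: per segregating site the
π contribution is 2p̂(1−p̂)·n/(n−1) at the site-wise n (pairwise deletion,
heterozygous calls treated as missing haploid states), summed and divided
by the region length L (gene span). θ_W = S/a₁/L with a₁ evaluated at the
harmonic-mean n over segregating sites through the digamma continuation
(identical to Σ1/i at integer n). Tajima's D uses the 1989 b/c/e constants
at that same n; groups with n < 4 or S = 0 report D as missing, never 0.
Absolute π and θ depend on the L convention; every ratio statistic is
invariant to it. Ratio flags: selection iff π_ratio > 4; a zero
denominator with nonzero numerator is flagged infinite, 0/0 undefined.

Neighbor joining is Saitou–Nei on IBS mismatch distances
(|dᵢ−dⱼ|/2 averaged over shared called variants, pairwise deletion),
Q-minimisation with ties broken by the lowest flattened index, negative
branch lengths clipped to zero, and the final two lineages joined at the
midpoint of the remaining edge (the tree is to be read as unrooted — all
tests compare path distances and bipartitions, which are invariant to
that choice). The monophyly check evaluates both sides of every edge,
including pendant edges, and returns the smallest side covering the label
set with its purity.

## The synthetic panel

The generator emulates the sampling structure the pipeline targets, with
one `numpy.random.Generator` seeded from `config.seed` (stream order:
reference, gene placement, variants, haplotype pools, haplotype draws,
heterozygosity/missingness, phenotype noise, expression noise).

* **Genome.** `n_chromosomes` × `chrom_length_bp` (default 3 × 2 Mb) of
  random sequence; a gene every 25 kb (span 4 kb, two CDS segments whose
  concatenation is a clean ORF — ATG, no internal stops, terminal stop —
  reverse-complemented on minus strands); `n_variants` (default 3,000)
  uniform positions, 2% 1-bp deletions.
* **LD blocks.** Variants group into `ld_block_bp` blocks (default 40 kb);
  each block carries 8 ancestral haplotypes; each accession draws one
  block haplotype from group-specific frequencies, dosage = 2 × allele
  (inbred), with 0.5% residual heterozygosity and `missing_rate` missing
  calls. Neutral blocks: each subpopulation uses 4 of the 8 haplotypes,
  disjoint subsets for a `structure_diff_fraction` of blocks (default 0.3,
  which makes PC1 separate the subpopulations); the wild outgroup draws
  uniformly from all 8, so it carries nearly all cultivated alleles.
* **Causal blocks.** Three of the eight haplotypes carry the
  trait-increasing allele. Target increasing-allele frequencies: wild
  0.25, lowland 0.45, upland 0.45 + `upland_pyramiding_boost`. The upland
  increasing mass rides one swept founder haplotype (90%), which is absent
  from lowland groups and ancestral in wild — the selective-sweep
  signature that produces the π-ratio and Tajima's D contrasts and makes
  the L-T-root designation (upland × ≥ 90% robust-allele carriage)
  recoverable as a tree cluster. Within the causal gene, the planted
  variant follows the increasing/other split exactly and the remaining
  ORF/promoter variants alternate between tagging that split and tagging
  the swept haplotype; intergenic block-mates tag the split with 10%
  per-haplotype flip noise (the clustered-significance signal); variants
  inside *other* genes' ORFs/promoters are balanced across the split so
  decoy genes do not inherit coding-level association. Planted coding
  variants are amino-acid-changing by construction (a 4-fold-degenerate
  site is nudged within its codon), since a causal coding allele that
  leaves the protein untouched would contradict its planted role.
* **Phenotype.** Sum of per-allele effects (`causal_effect_sd` per copy,
  zero when `trait_h2 = 0`), a subpopulation shift
  (`structure_shift_sd`), and Gaussian noise scaled so the planted genetic
  variance is `trait_h2` of the total; wild accessions are unphenotyped.
  `realized_h2` verifies the generator hits the target within sampling
  error (0.40–0.60 at the default 0.5).
* **Expression.** 6 robust + 6 control varieties × root/shoot × 2
  replicates, lognormal baselines with 15% multiplicative noise; causal
  genes get a planted robust/control root ratio of 2.0, every third causal
  gene is instead root-specific (root ≈ 5 RPKM, shoot ≈ 0.05).
* **Linkage QTLs.** Intervals ±50 kb around ~60% of causal genes with
  parents chosen to differ at the planted variant, plus decoy intervals.

What the generator does **not** emulate: coalescent demography,
recombination within blocks, epistasis, genotype-calling error structure,
multiallelic variation, and realistic expression count noise. Passing
tests therefore demonstrate the statistical machinery and the screening
logic, not calibration against real rice data; the published panel-scale
counts (e.g. 21 RL QTLs from 795 accessions and 3.3M SNPs) are not
reproducible at this scale and are not targeted.

## Problem sizes used in the checks

The statistical acceptance checks run at desk scale by design: the GLM
oracle on 50 × 200; null calibration at 2,000 variants and 20 structured
seeds; family-wise error over 200 datasets of 100 accessions × 2,000
variants with 200 permutations each; planted-gene recovery on 10 default
panels (600 accessions × 3,000 variants, 200 permutations); the pyramiding
gradient on 10 light panels. The whole suite completes in roughly eight
minutes on one CPU.
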