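# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `haploqtl`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Phenotype model

Plot observations follow

y(plot) = μ + g_i + b_k + ε,    ε ~ N(0, σ²_t),

for accession *i* in incomplete block *k* at measurement time point *t*.
Block adjustment subtracts (block mean − grand mean) from every plot —
the equal-block-mean assumption, justified because block membership is
randomized — after which the design is treated as completely randomized and
analysed per accession with y_i = μ + g_i + ε_i. The adjustment is applied
globally (all blocks of both replicates and both experiment groups are
centred to one grand mean); since experiment groups are unions of blocks,
any group-environment shift is removed by the same operation.

Variance components come from balanced one-way ANOVA moments:
σ̂² = MS_error, σ̂²_g = max(0, (MS_accession − MS_error)/r). For a balanced
design with non-negative components these are exactly the REML estimates,
so no iterative fit is needed and the estimator is exactly testable.
Heritability is h² = σ²_g/(σ²_g + σ²/r); it is invariant to affine
transformation of the trait and clamped to [0, 1] by construction.
Accessions missing a replicate are dropped from component estimation (the
threshold is configurable). Among the nine repeated measurements the one
with the highest ĥ² represents the trait downstream, ties going to the
earliest time point.

The chlorophyll index is implemented as the reciprocal difference
CHL = 1/R₇₀₀ − 1/R_NIR. This is the red-edge chlorophyll index family
member consistent with the observed CHL scale (values of 1.2–4.8 require
reciprocal reflectances). Subpopulation mean separation uses one-way ANOVA
followed by all-pairs Tukey HSD at α = 0.05 with compact-letter display
(insert-and-absorb on groups ordered by mean); Tukey is the standard choice
for germplasm mean separation.

## SNPLDB markers

SNPs pass a minor-allele floor of 2%: a SNP is kept when its minor-allele
carrier count is at least ⌊0.02 · n⌋ (six carriers in a 341-accession
panel). LD blocks follow the Gabriel confidence-interval rule: the |D′| CI
for each SNP pair is read off a likelihood grid on [0, 1] at step 0.001 with
5% tails, allele frequencies fixed at their MLEs and the sign of D at its
MLE; a pair is "strong LD" when CI_low ≥ 0.70 and CI_high ≥ 0.98, and
"recombination evidence" when CI_high < 0.90. A candidate interval becomes a
block when its outermost pair is strong, ≥95% of its informative pairs are
strong, and its span is ≤100 kb (block size additionally capped at 25 SNPs
to bound the pair enumeration); candidates are accepted greedily from
largest to smallest. SNPs in no block ride along as biallelic singleton
markers.

Within a block each distinct haplotype string is an allele. Haplotypes
below the 2% frequency floor are merged into the common haplotype at
smallest Hamming distance (ties to the more frequent haplotype, then
lexicographic — fully deterministic). An accession with more than 20% of a
block's SNPs missing is coded missing at the marker; below that, missing
SNPs are imputed to the per-SNP major allele. Markers left with fewer than
two alleles are dropped.

Genetic similarity between accessions is the proportion of jointly called
markers at which they carry the same haplotype allele. For the structure
covariates the similarity matrix is **double-centred** (Gower, as in
principal-coordinate analysis) before eigendecomposition: the raw matrix's
leading eigenvector is near-constant (mean relatedness), collinear with the
model intercept, and carries no structure information, whereas the centred
leading eigenvectors separate the subpopulations by sign. Eigenvectors are
selected by cumulative share (default 50%) of the positive spectrum,
**capped at 10** — the conventional number of structure axes in
eigenvector-corrected GWAS. The cap matters because a weakly structured
panel has a nearly flat centred spectrum, and the share rule alone would
select a large noise subspace that absorbs genuine marker signal.

## Two-stage multi-locus scan

Model: y = 1μ + W a + X b + e on block-adjusted accession means (the
balanced-design sufficient statistic). A k-allele marker contributes k−1
indicator columns against its most frequent allele; missing marker calls are
coded as the reference. Stage 1 fits each marker alone and keeps those with
partial-F p ≤ α₁ = 0.05. Stage 2 is forward selection (add the candidate
with the smallest partial-F p given the current model, ties to the larger F
then ascending genome order, if p ≤ α = 0.05) with backward elimination
after every addition (repeatedly drop the worst included marker with
p > α). Candidates adding no column rank are skipped, which also guarantees
that duplicated markers enter at most once. No multiplicity adjustment is
applied at either stage: the multi-locus model is the built-in control, and
0.05 is used as the working level throughout.

Per-locus statistics are computed in the final joint model: −lg P from the
marker's partial F-test; allele effects as the least-squares coefficients
re-expressed as deviations with frequency-weighted zero sum (so effects are
comparable across loci regardless of reference-allele choice); and R² as
the sequential (entry-order) incremental sum of squares over the corrected
total SS. Sequential rather than partial SS is used so that per-locus
contributions sum *exactly* to the joint marker R² — the additivity that the
acceptance checks exercise on the bundled published tables. Rank decisions
use an SVD basis with tolerance 1e-8·max(n, p)·σ₁.

A caution documented by measurement (see the decisions record accompanying
development): with hundreds of null markers, stepwise selection at a raw
α = 0.05 retains roughly α·m_null·P(persist) null loci, because a marker
pre-selected for its chance correlation with the never-modelled residual
(polygenic background + error) keeps about half of that correlation in the
joint model. On the default simulated panel (~690 markers) about half of the
reported loci are such false positives even though essentially all true loci
are found. Users who need a conservative locus list should tighten α or
validate loci on an independent sample; the package deliberately implements
the plain forward–backward rule rather than silently correcting it.

## Synthetic-data generator

The generator is the package's study stand-in, not a fixture. Genome:
20 chromosomes of 50 Mb carrying 2,000 SNPs in blocks (30% singletons;
multi-SNP blocks of 2–12 SNPs spanning ~20 kb on average, mean gap set by
the chromosome length). Each block's haplotype pool is built by sequential
single-SNP mutation — a perfect phylogeny — so within-block SNP pairs pass
the four-gamete test (|D′| = 1) while distinct blocks segregate
independently; pool sizes are 2 + Poisson(1.1) capped at min(k+1, 11),
matching the 2–11 alleles-per-marker range with a mean near 3.

Subpopulations: WA accessions sample block haplotypes from Dirichlet pool
frequencies (floored at 4%); LR derives from the realised WA frequencies by
a Dirichlet drift step (concentration 30), and RC from LR likewise. Planted
events edit chosen QTL blocks: *emerged* alleles are novel single-mutation
haplotypes introduced at 8% frequency (the reported emerged-allele
frequencies run 3.4–13.6%); *excluded* alleles are zeroed out; *recovered*
alleles are LR-excluded wild alleles restored in RC. Defaults mirror the
NDVI accounting pattern: 2 emerged + 3 excluded (LR vs WA), 2 emerged + 2
excluded + 2 recovered (RC vs LR), implying 4 emerged + 1 excluded for
LR+RC vs WA. On QTL blocks the sampled counts are deterministically
adjusted so every intended-present allele has ≥2 carriers per subpopulation
and every intended-absent allele has none — the planted ledger is then
*exactly* recoverable by the accounting, which is what the recovery tests
assert. Optionally a planted emergence is placed at a "new locus"
(monomorphic in all ancestral subpopulations).

Trait architecture: 10 additive QTLs; allele effects are drawn N(0, 1),
centred to zero sum per locus, then scaled so that **every locus contributes
an equal share** of the QTL variance and the summed QTL values have SD 0.02
on the trait scale (NDVI-like, mean 0.11). Equal shares are a deliberate
identifiability choice: with iid random effects some loci contribute
arbitrarily little variance and recovery tests would measure the luck of
the draw rather than the method. The polygenic residual is orthogonalised
against the QTL values and rescaled so the realised genotypic variance hits
the target exactly; with QTLs at 50% of the phenotypic variance and
h² = 0.75, half the genetic variance is deliberately left unmapped,
mirroring the undetected share seen in real panels. Per-time-point error
variances follow a U-shaped multiplier schedule
(19, 10, 6, 3, 1.8, 1, 1.4, 2.5, 5) whose minimum at index 5 designates the
best measurement and sweeps per-time-point heritability from ≈0.16 to the
target — the shape is free since only ranges are reported for the real
data.

What the generator does **not** emulate: coalescent genealogy and
recombination-driven between-block LD, genotyping error, shared missingness
patterns, and genuine environmental trends across time points. Tests passing
on this generator therefore certify the algorithmic chain (marker assembly,
scan, accounting, cross prediction), not robustness to those real-data
features.

## Cross simulation

Progeny are recombinant inbred lines at fixation: along each chromosome the
parental origin of consecutive loci follows a two-state Markov chain with
switch probability R = 2r/(1+2r), r = (1 − e^(−2d))/2 (Haldane), and
d = Δbp · 2.2 cM/Mb — the soybean genome-wide average; the map rate is
configurable because the underlying linkage model prescribes none.
Chromosome starts are fair coin flips (implemented by accumulating XOR
switches with probability ½ at boundaries, which makes chromosomes exactly
independent). Percentiles use the nearest-rank definition
(⌈p/100·n⌉-th order statistic) for determinism; predicted line values are
μ̂ (the grand mean of adjusted phenotypes) plus summed carried-allele
effects, so the maximum attainable prediction is bounded by the per-locus
best parental alleles — the transgression bound asserted in the tests. All
C(n, 2) = n(n−1)/2 crosses are enumerated (57,970 for n = 341); the
pipeline can subsample crosses for runtime, with the subsample drawn from
the run's single seed.

## Problem sizes used by the checks

The acceptance script and test suite run the generator at its defaults
(341/340 accessions, 2,000 SNPs → ≈690 markers, 10 QTLs) for QTL recovery;
heritability recovery uses a 400-SNP panel with 200 phenotype redraws;
oracle-equivalence instances use 40–90 accessions and ≤12 markers; RIL and
type-I-error checks use 2,000 lines / 2,000 markers. These sizes are the
package's chosen desk-scale study conditions and are fixed in the scripts.

## Known limitations

* The scan's false-discovery behaviour at raw α = 0.05 is documented above;
  no FDR/Bonferroni option is currently exposed.
* Missing-genotype handling in the association design codes missing as the
  reference allele; panels with substantial non-random missingness should be
  imputed upstream.
* `estimate_components` assumes the post-adjustment design is balanced;
  heavily unbalanced data get accessions dropped, not a general mixed-model
  fit.
* The run summary records seed and configuration hash once per run
  (`summary.json`) rather than stamping every TSV.
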