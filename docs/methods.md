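# Methods

This note documents the statistical model behind `quadrec`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the problem sizes used by the test suite and the
acceptance script.

## Inherited-event model

A *biallelic event* in a child is either a homozygous rare coding variant or
a compound-heterozygous pair in one autosomal gene; an *X-linked hemizygous
event* is a maternally transmitted variant on an affected male's single X.
Phasing is pedigree-based only (no read-backed phasing): a het/het pair is
accepted as in trans exactly when one variant is carried solely by the
father and the other solely by the mother. When any single parent carries
both variants a cis configuration cannot be excluded, so the pair is
discarded and tallied under `phase_ambiguous`. This is conservative: true
trans pairs with a doubly-carrier parent are lost, but no cis pair is ever
counted. A homozygous child call with a non-carrier parent, or a het call
carried by neither parent, is a Mendelian inconsistency (plausibly a de novo
or a genotyping error) and is rejected with its own tally, so that
retained + shared + phase-ambiguous + rejected always accounts for every
candidate. An exhaustive test enumerates all quad genotype configurations
with up to three variants per gene and checks the caller against brute-force
enumeration of parental-origin assignments.

Functional grouping: PTV + PTV and PTV + Dmis pairs are PTV events (a single
intact allele remains in either case), Dmis + Dmis are Dmis events,
synonymous + synonymous the negative control; other mixtures (e.g.
PTV + synonymous) do not constitute a biallelic genotype of interest. When a
gene supports several candidate events in one child, the child contributes
one event for that gene in the strongest group (PTV > Dmis > synonymous),
since burden counts carriers, not variant pairs.

Rarity is enforced on both frequency sources at once: the cohort-side allele
frequency is computed over *parental* chromosomes only (children's alleles
are copies of parental alleles and would be double-counted; fathers
contribute one X, mothers two), and both it and the reference-population
frequency must be ≤ 1% (autosomes) or ≤ 0.1% (X). Thresholds are inclusive.

## Burden testing

Carrier counts are contrasted with a two-sided Fisher exact test
(minimum-likelihood-sum convention, as in R's `fisher.test`). The reported
odds ratio is the sample cross-product ratio, not the conditional MLE — the
two differ for extreme tables, and the cross-product form is what the
published carrier tables print. The 95% CI is the exact conditional
(noncentral hypergeometric) interval; this choice is validated by a unit
test in which the interval for the 10-vs-2-of-1799 table reproduces the
published 1.07–47.19 exactly. No multiple-testing correction is applied
across the six groups; raw p-values are reported. X-linked denominators are
male children only.

`two_list_fisher` is the same 2×2 machinery applied to gene-list membership
(functional clusters, expression modules, neuron classes), with the full
list sizes as denominators.

## Permutation test for RIG–DNG connectivity

Genes with higher background de novo mutation rates and longer coding
sequences have more recorded interactions and co-expression partners, so an
unmatched null would overstate enrichment. The null here redraws a
size-matched replacement for the RIG set within strata formed by the
5 × 5 grid of dnv-rate and coding-length quintiles over the gene universe
(the covariate table minus the DNG set), sampling without replacement;
strata too small for their quota are merged with the nearest stratum on the
flattened grid and the merge is logged. Both statistics — the number of
DNGs touched and the number of RIG–DNG edges — are compared to the null
with the add-one empirical p-value, p = (1 + #{null ≥ obs})/(1 + n\_perm).
Whether to permute RIGs or DNGs, the bin count and n\_perm are not dictated
by the analysis being reproduced; RIG-permutation with 5 × 5 bins and
n\_perm = 1000 are the defaults, all configurable.

## Co-expression modules

The module detector follows the hybrid WGCNA recipe: Pearson correlation →
soft-threshold adjacency → topological overlap (TOM) → average-linkage
clustering of 1 − TOM → static cut → minimum module size (default 10), with
module eigengenes as the first principal component of the standardized
module submatrix (signed to correlate positively with the module mean).

Two numerical choices matter and were made deliberately:

* **Signed-hybrid adjacency** (a = r^β for r > 0, else 0). An unsigned
  network (|r|^β) cannot separate anti-correlated expression programs at
  all — two perfectly anti-correlated blocks produce an all-ones adjacency —
  yet prenatal-high and postnatal-high trajectories are exactly such a pair.
  A fully signed transform (((1+r)/2)^β) fails differently at the low powers
  used here (β = 4 spatiotemporal, β = 3 laminar): uncorrelated pairs retain
  adjacency 0.5^β ≈ 0.06, which inflates TOM between modules and noise until
  everything merges (measured: ARI 0 on planted r = 0.8 blocks). The
  signed-hybrid form sends uncorrelated pairs to ≈ 0, recovers planted
  blocks exactly, and leaves white-noise genes unassigned.
* **Static absolute cut at height 0.9** on the 1 − TOM scale (the
  `cutreeStatic` convention). A cut *relative* to the tree height cannot
  leave noise genes unassigned — the giant cluster always survives a
  relative cut. Full dynamic hybrid tree cutting, soft-threshold selection
  by scale-free fit, blockwise decomposition and eigengene-based module
  merging are out of scope; the static cut plus minimum size is the
  documented simplification.

Neuron-class calls use a two-sided Wilcoxon rank-sum test (exact null
distribution when untied) on per-neuron-type mean expression, 24 excitatory
vs 45 inhibitory types by default, α = 0.05 (not dictated by the reproduced
analysis; configurable). Direction of the mean difference gives the class.

## Synthetic data: what it emulates, and what it does not

The cohort generator reproduces the statistical structure the analysis
assumes: 1799 quads by default, probands 87.3% male and siblings 47.1% male,
Mendelian transmission with correct X ploidy, per-group sibling carrier
rates equal to the published sibling-specific counts (19/1799 biallelic PTV
… 202/847 X synonymous), shared proband–sibling events at the published
shared-row rates, and a proband excess in constrained brain-expressed genes
expressed as carrier odds ratios (defaults 5.02 biallelic PTV, 3.13 X
PTV — the published constrained-gene effects; 1.0 gives a null cohort).

Two generator properties make it a usable oracle rather than a realistic
sequencing simulator:

* **All qualifying events are planted.** Background rare variants in
  qualifying categories are laid down with at most one carrier parent per
  family and gene (and on the X, carried by fathers, whose X never reaches a
  son), so they cannot assemble into chance biallelic or hemizygous events.
  Consequently the planted rates realize the target odds ratios exactly in
  expectation, and the truth manifest lists every event the pipeline should
  call — the basis of the manifest-replay tests and the planted-OR recovery
  check.
* **Sibling genotypes at proband-specific events are drawn conditional on
  the sibling not reproducing the event** (and vice versa). Unconditional
  transmission would convert a quarter of planted homozygous events into
  shared events, which the pipeline then removes, deflating realized rates.
  Shared events are planted separately at their own rates.

Real exome data differs in ways the generator does not model: linkage
disequilibrium, genotyping error beyond a uniform missingness rate,
population stratification of allele frequencies, variable per-gene variant
density correlated with gene length, and chance recessive events in
controls. Passing the synthetic tests therefore demonstrates that the
pipeline's logic and statistics are correct under the stated model, not
that the published gene lists would be recovered from raw data — the
published 21-candidate list, the 58-DNG/37-RIG network and similar
cohort-scale results require the original restricted datasets.

MAFs for background variants follow a truncated Beta(0.3, 3000) (median ≈
singleton scale, capped at 0.5%), with a 20% admixture of common variants
(1.5–5%) that must be removed by the MAF filter; 2% of background variants
fail one quality flag, and sparse missingness is injected at rate 0.002.
Planted X-event variants cap their reference frequency at 0.05% so a planted
event is never contradicted by its own rarity filter.

The expression generator builds each module from a latent factor (a
stage- or layer-dependent trend plus noise); gene i is
√ρ·f + √(1−ρ)·σ·ε, so the expected within-module correlation is ρ at σ = 1
and exactly 1 at σ = 0. The PPI generator is Erdős–Rényi with RIG–DNG pairs
wired at `background_edge_p × enrichment_factor` and confidence scores ≥ 400
on wired edges plus sub-threshold decoys.

## Calibration checks and problem sizes

The statistical acceptance tests run at the following sizes, chosen to give
stable checks at interactive cost:

* **Null burden calibration**: 200 replicate cohorts of 2000 quads
  (300 genes, light background). Fisher's exact p is discrete and
  conservative — its null distribution is stochastically *larger* than
  uniform — so "p-values are uniform" is operationalized as (a) a one-sided
  KS test against anti-conservatism and (b) the type-I error rate at
  α = 0.05 inside its 99% binomial band. A two-sided KS against U(0,1)
  rejects for any exact conditional test, by construction.
* **Planted-OR recovery**: 200 cohorts of 1799 quads with OR 5.0 planted at
  the published constrained carrier rates (~10 vs 2 per cohort); the pooled
  cross-product OR's 95% CI must bracket 5.0.
* **Permutation test**: type-I error over 200 null PPI cohorts at
  n_perm = 199 (rejection at p ≤ 0.05 is exact when α(n+1) is integral);
  power ≥ 90% over 40 cohorts at enrichment 3 and n_perm = 1000.
* **Module recovery**: ARI ≥ 0.9 on five replicates of the default
  two-module spec (r = 0.8, 200 samples); exact recovery of noiseless
  anti-correlated blocks; ≥ 80% unassigned on white noise.

The acceptance script reuses the same machinery at reporting scale: one
full 1799-quad cohort through the file-based pipeline (manifest replay and
candidate recovery), 20 further cohorts pooled for OR recovery, 20/50
replicates for permutation power/calibration.

## Known limitations

* Phase-ambiguous compound hets are discarded, so biallelic carrier counts
  are a lower bound in genes with shared parental haplotypes.
* The cohort allele frequency treats families as unrelated founders;
  cryptic relatedness would deflate it.
* The module detector's static cut does not adapt to heterogeneous module
  tightness; very unequal module sizes may need a different `cut_height`.
* Quality flags are consumed as precomputed booleans; the depth/GQ/call-rate
  thresholds themselves are applied upstream of this package.
* `carrier_fraction` reports the fraction of probands carrying events in
  candidate genes; it does not attempt attributable-risk estimation.
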