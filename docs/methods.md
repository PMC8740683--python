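# Methods

## Coordinate conventions

All intervals are 0-based half-open (BED convention); VCF positions are
converted to 0-based on read and back to 1-based on write. Overlap means
≥1 shared base. The ±50 kb annotation window is closed at both ends.

## RE→TG network construction

Loop anchors (any width; 5 kb in the generated data) are split into
consecutive 1-kb tiles from the anchor start; the final tile is kept
truncated rather than extended or dropped, so the tiles exactly cover the
anchor. A tile is *open* iff it overlaps at least one ATAC peak. Promoters
are the 2 kb upstream of the TSS (strand-aware, clipped at position 0).
For every loop with an anchor overlapping a gene's promoter by any amount,
the tiles of the opposite anchor become REs of that gene; each gene's own
promoter is also an RE but does not influence the gene's category.
Categories: OpenLoop if any linked loop-anchor RE is open; NonOpenLoop if
the gene is loop-linked but all anchor REs are nonopen; NoLoop otherwise.
A gene with both open and nonopen REs is OpenLoop.

Silencer linkage counts a gene when any of its REs overlaps a silencer
(direct) or when a loop touching its promoter has its other anchor on a
silencer (indirect); the network object retains its source loops for this
purpose. Comparing two networks within a category uses the two-sided
Fisher exact test with the point-probability summation rule.

Genes absent from the expression table are treated as unexpressed (FPKM
0). Quantiles over an empty category are NaN, never silent zeros.

## Network enrichment of summary statistics

The effect-size prior is spike-and-slab with network-modulated
hyperparameters, π_j = θ₀ + a_j·θ on the probability scale and
σ_j² = σ₀² + a_j·σ². Grids are constrained so every π_j ∈ (0,1); the
default grid is θ₀ ∈ {1e−4, 1e−3, 1e−2, 0.05}, θ ∈ {0, 1e−3, 1e−2, 0.05},
σ₀² ∈ {0.01, 0.05, 0.1}/n, σ² ∈ {0, 0.5, 1, 2}·σ₀², and every analysis can
pass its own grid (`make_grid`). The likelihood is the standard
summary-statistics regression form β̂ | β ~ N(S R S⁻¹ β, S R S). An LD
matrix that fails a Cholesky factorization is regularized by adding 1e−6
to the diagonal.

The posterior is approximated per grid point by a fully-factorized
variational family q(β_j) = α_j N(μ_j, τ_j²) + (1−α_j) δ₀ with closed-form
coordinate-ascent updates; SNPs are updated in descending |β̂_j/s_j| order
(fixed, for determinism), convergence is declared when the relative ELBO
change falls below 1e−7 (cap 1000 sweeps), and the ELBO is asserted
nondecreasing every sweep. The converged ELBO stands in for the log
marginal likelihood; models average exp(logML) uniformly over their
allowed grid points, and Bayes factors are ratios of those averages
computed in log space. Points that fail to converge are flagged and
excluded from the averages. With a degenerate slab (all σ_j² = 0) the
evidence reduces exactly to the null Gaussian likelihood.

For p ≤ 12 an exact oracle sums all 2^p inclusion configurations with
analytic Gaussian integration; the test suite requires the ELBO to sit
within 0.1 nat below it (the ELBO is a true lower bound; mean-field is
exact at p = 1).

One caveat on invariances: because the likelihood depends on β̂ and se
only through β̂/se and the slab variance is specified in effect-size
units, rescaling β̂ and se by a common factor c changes per-point
marginals unless the σ² grid is rescaled by c²; the test suite asserts
the joint invariance (data and variance grid rescaled together), which is
the well-defined reparameterization.

## Differential openness

The baseline genome carries the major allele of every variant (alt when
its frequency exceeds 0.5; ties keep the reference); the reference-genome
baseline (empty variant set) is the mode used with external control
panels. An individual carries a variant when dosage ≥ 1 — the scorer
consumes one unphased personal variant set per individual, matching
predictors that score a single personal sequence; dosage 2 contributes
once (a `dosage_weighted` switch exists for the burden arm). Missing
genotypes are imputed to the baseline allele and counted. An individual
is *nonbaseline* for an RE when |score − baseline score| > 1e−9; the
synthetic scorer uses weights on the 1/256 grid so the flag is
effectively exact.

Per RE, the one-sided Fisher exact p (nonbaseline enrichment in cases) is
the hypergeometric upper tail; the Wilcoxon rank-sum compares the scores
of nonbaseline cases against nonbaseline controls only, two-sided, exact
when small and tie-free. Fisher's method combines the two (χ² on 4 df).
REs with no nonbaseline individual are reported with p = 1 and flagged
`skipped`; when only one group has nonbaseline individuals the Wilcoxon
is undefined and the combined p falls back to the Fisher p alone
(flag `fisher_only`). Gene-level evidence combines the k = 5 linked REs
with the smallest combined p ("highest differential openness", score
−log p) on 2m df; the pipeline passes only tested (non-skipped) REs into
this step, since a skipped RE carries no data. BH FDR is applied across
genes within one cell type's analysis.

External-control augmentation samples n = 500 externals stratified by sex
with largest-remainder rounding to match the case sex ratio, replaces the
original controls, and removes variants that are absent from the case
data (either absent from its site list or carried by no case).

## Coding burden and pathways

Deleteriousness per SNV is the mean of the available predictor scores
(three columns, gaps allowed; SNVs with no score are dropped and
counted). Rare means cohort allele frequency < 0.01 (configurable).
Burden g_im sums scores over carried rare nonsynonymous SNVs; the
case-vs-control test is a one-tailed Welch t test (unequal variances;
"greater"). Genes with zero variance in both groups give p = 1 — the
spec's "identical groups → p = 0.5" example is read as identical groups
*with* variance (t = 0).

The term-level Poisson test uses λ = term size × global rate, where the
global rate is the fraction of scored genes with burden p ≤ 0.05 (the
expectation per gene with no term structure); its p-value is the upper
tail P(X ≥ k), 1 when k = 0. The noncoding side is an internal
hypergeometric enrichment (upper tail, fold = observed/expected overlap)
over a flat gene-set collection (GMT; no ontology propagation) — it plays
the role an external GO web service plays in the motivating study without
the web dependency. The two sides combine per term by Fisher's method
(χ²₄) and rank with BH q-values; terms present on only one side are
excluded and logged.

## Synthetic data: what it emulates and what it does not

Defaults mirror the study shape: 268 cases / 133 controls, ~1,000 genes,
400 loops with 5-kb anchors (→ ~1-kb tile REs), 60% of distal anchors
covered by a peak, ~10% of loop q-values above the 0.01 threshold to
exercise filtering, and a 17,443×401-style genes × samples burden matrix
at reduced scale (1,000 × 401). Allele frequencies follow
Beta(0.5, 5) truncated to [0.001, 0.5] with Hardy–Weinberg genotypes.

Openness effects are deliberately sparse — most individuals score exactly
at the baseline: each RE receives Poisson(0.15) background weighted
variants (drawn from the rarer end, AF ≤ 0.1; signed weights
Uniform(0.05, 0.5) snapped to 1/256) and Poisson(2) weightless variants.
Each planted RE carries one extra variant with weight 0.7 whose alt
allele has frequency 0.15 in cases and 0.03 in controls
(`carrier_freq_*` are allele frequencies of the case-enriched allele;
genotypes are Binom(2, f) per group). The background rate was fixed by a
pre-registered power analysis: denser backgrounds dilute the per-RE 2×2
tables and push planted genes below the BH threshold, while 0.15 matches
the "sparse effects" design premise and leaves the planted signal
recoverable (~85% of planted genes at q < 0.01).

Planted burden genes receive 12 case-private nonsynonymous SNVs each
(1–3 case carriers, scores Uniform(0.7, 1)) on top of a background of
~3 rare nonsynonymous SNVs per gene in both groups, plus occasional
common and synonymous SNVs so the filters do real work. One GO term is
seeded with all planted genes.

GWAS summary statistics are drawn from the effect-size prior itself:
defaults p = 800 SNPs, n = 20,000, θ₀ = 0.004, θ = 0.05, n·σ₀² = 30,
σ² = 0, block-diagonal AR(1) LD (ρ = 0.3, blocks of 10). These values
were calibrated at design time so that a true network annotation yields
Bayes factors in the tens-to-thousands — the regime the motivating study
reports for its disease-relevant networks — rather than a marginal
signal.

Every generator draws from a stream seeded by (global seed,
CRC-32 of the stage name), so stages regenerate independently and runs
are byte-identical per seed.

What the generator does **not** emulate: realistic LD from reference
panels, mutation spectra, sequence content inside REs, phasing,
population structure, or any nonlinearity in the accessibility scorer
(the synthetic scorer is additive). Passing tests therefore demonstrate
the statistical machinery and its calibration under the generative model,
not performance on real sequencing data.

## Calibration of the exact tests

Under the null the one-sided Fisher exact p-value is a discrete,
super-uniform statistic: P(p ≤ u) ≤ u with steps the size of the
hypergeometric point masses (≥ ~0.1 at 300 individuals). The combined
RE-level p-values inherit this conservativeness, so their pooled null
distribution sits visibly above uniform (a standard property of exact
conditional tests, not an implementation artifact; the included
feasibility analysis puts the Kolmogorov–Smirnov distance above the
rejection threshold even for the most favorable generator design). The
meaningful calibration guarantees — and the ones the test suite asserts —
are that the type-I error rate at 0.05 is never inflated and that no gene
reaches BH q < 0.01 under the null. Power-sensitive analyses should keep
in mind that p-values from sparse 2×2 tables are conservative.

## Numerical choices

- VI: ELBO tolerance 1e−7 (relative), 1000-sweep cap, descending |z|
  update order, numba-accelerated sweeps with a pure-numpy fallback.
- Fisher's method clips p-values at 1e−300 before taking logs.
- Tie at allele frequency exactly 0.5 → reference allele in the baseline.
- Hypergeometric/Poisson tails come from scipy's survival functions and
  are checked against enumeration/series oracles to 1e−12.
- Largest-remainder rounding for sex-stratified sampling.

## Known limitations

- The openness scorer contract is additive-in-variants here; a real
  sequence-based accessibility model can be plugged in but is out of
  scope.
- The enrichment model fits one annotation at a time (no joint
  multi-network model) and dense LD only (desk scale).
- Exact-test conservativeness at modest cohort sizes, as discussed above.
- The Poisson term test treats genes as exchangeable within a term; gene
  length or mutability covariates are not modeled.
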