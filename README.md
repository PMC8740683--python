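# retgnet

Integrative genetic analysis of a case/control disease cohort through
cell-type-specific regulatory networks, modeled on the kind of study that
combines H3K27ac HiChIP enhancer–promoter contacts, ATAC-seq open
chromatin, whole-genome sequencing and GWAS summary statistics to
implicate disease genes and pathways (the motivating application is
abdominal aortic aneurysm in aortic smooth muscle and endothelial cells).
It is a library: the importable API plus the narrative scripts under
`examples/` are the interface.

The package implements five connected analyses:

1. **Regulatory-element → target-gene (RE→TG) networks.** Loop calls
   (BEDPE with q-values, kept at q < 0.01) have their anchors split into
   1-kb tiles; a tile is *open* when it overlaps ≥1 ATAC peak. A gene whose
   promoter (2 kb upstream of the TSS) is touched by one anchor inherits
   the tiles of the opposite anchor as its REs. Genes are categorized
   OpenLoop / NonOpenLoop / NoLoop, with expression-quantile summaries and
   silencer-linkage statistics (Fisher exact).
2. **Bayesian network enrichment of GWAS summary statistics.** Per-SNP
   effects follow a spike-and-slab prior whose inclusion probability and
   slab variance shift for annotated SNPs,

       β_j ~ π_j N(0, σ_j²) + (1 − π_j) δ₀,
       π_j = θ₀ + a_j θ,   σ_j² = σ₀² + a_j σ²,

   with a_j = 1 iff SNP j lies within ±50 kb of any network RE or target
   gene. The prior is combined with the summary-statistics likelihood
   β̂ ~ N(S R S⁻¹ β, S R S) (S = diag(se), R = LD), fitted by mean-field
   coordinate-ascent variational inference over a hyperparameter grid.
   Enrichment strength is the Bayes factor of M1 (θ>0 or σ²>0), M11
   (θ>0, σ²=0) or M12 (θ>0, σ²>0) against the baseline M0 (θ=0, σ²=0).
   An exact 2^p enumeration oracle cross-checks the fit for small p.
3. **Differential chromatin openness from personal genomes.** Every
   individual's variants inside each RE are scored by a pluggable
   openness scorer and compared with a baseline genome (major-allele or
   reference). Per RE: one-sided Fisher exact on nonbaseline counts
   (enrichment in cases) plus two-sided Wilcoxon rank-sum on nonbaseline
   scores, combined by Fisher's method (χ²₄); per gene: the top-5 REs by
   combined evidence, combined again (χ²_{2m}) with Benjamini–Hochberg FDR.
   External control augmentation preserves the case sex ratio and drops
   variants absent from the case data.
4. **Coding mutation burden.** g_im = Σ_j s_ijm sums averaged
   deleteriousness scores (three predictors, mean of those available) over
   the rare (AF < 0.01) nonsynonymous SNVs of gene i carried by sample m;
   per gene a one-tailed Welch t test asks whether cases carry more.
5. **Pathway combination.** Per GO term, a Poisson tail test on the count
   of nominally significant burden genes and a hypergeometric test on
   differential-openness target genes, combined by Fisher's method and
   ranked with BH q-values.

A first-class synthetic-data module (`retgnet.simulate`) generates every
input with planted ground truth — case-enriched openness alleles in
selected REs, high-burden genes with case-private deleterious SNVs, an
enriched GO term, and GWAS summary statistics drawn from the effect-size
prior — so the full pipeline is testable offline.

## Worked example

`python examples/05_full_pipeline.py` generates the default study
(268 cases, 133 controls, ~1000 genes, 400 loops, 20 planted REs with a
0.7-weight case-enriched allele at frequency 0.15 vs 0.03) and runs
everything:

```
tables written to pipeline_out
{
 "n_significant_genes": 17,
 "planted_gene_recovery": 0.85,
 "planted_burden_top_decile": 1.0,
 "planted_term_rank": 1,
 "n_genes_tested": 285
}
```

Seventeen genes reach BH q < 0.01, 85% of the planted target genes are
among them, every planted burden gene sits in the smallest decile of
coding p-values, and the planted GO term tops the combined ranking.

`python examples/03_gwas_enrichment.py` shows the enrichment arm:

```
261/800 SNPs within 50 kb of a network RE or target gene
simulated at theta0=0.004, theta=0.05, 17 causal SNPs
BF(M11:M0) network    =    1083.49
BF(M11:M0) permuted   =       0.26
BF(M12:M0) network    =    1196.75
BF(M12:M0) permuted   =       0.10
BF(M1:M0) network    =     977.86
BF(M1:M0) permuted   =       0.23
```

The true network's Bayes factor is three to four orders of magnitude
above the permuted-annotation control, the qualitative signature of a
disease-relevant regulatory network.

The other examples cover network construction and expression summaries
(`01`), the differential-openness arm with per-gene tables (`02`), and
coding burden plus pathway combination (`04`).

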