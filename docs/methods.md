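# Methods

## Statistic and estimators

The association statistic for cell type *c* in tissue *t* is

    z_c = Σ_p sd(X_p) · z_p · M_{p,c} / sd(F̂_c),      M = β̂_t S_t (S_tᵀS_t)⁻¹,

the summary-statistic form of regressing the trait on the deconvolved GRP
`F̂ = X β̂ S (SᵀS)⁻¹`. Its derivation assumes (i) signature gene expression
is similar across individuals (the standard deconvolution assumption),
(ii) only cis-eQTL effects contribute, and (iii) any single SNP or cell type
explains a small share of trait variance, so the (1 − R²) factors in the
exact variance expressions can be dropped. Substituting
`z_p ≈ √n · cor(X_p, Y)` shows `z_c ≈ √n · cor(F̂_c, Y)`: the statistic is
asymptotically the individual-level OLS z-score, which is what the
summary–individual agreement test verifies (Pearson r > 0.99 at n = 5,000).

Estimator conventions, where the derivation is silent:

* `sd(X_p)` and `sd(F̂_c)` are sample standard deviations (denominator
  n − 1) over the same reference panel — both appear in one formula and must
  share a population.
* `B̂` enters deconvolution uncentered and intercept-free, matching the
  estimator's algebra; covariate adjustment of imputed expression is exposed
  as an optional upstream step, default off.
* `A = (SᵀS)⁻¹` is computed by Cholesky solve and symmetrized. A condition
  number of SᵀS above `cond_max` (default 1e8) is an error instructing the
  user to revise the gene set or merge collinear cell types; the
  pseudo-inverse fallback is reserved for Cholesky failures below that
  threshold. Fewer than 50 signature genes is an error unless forced.
* Weight SNPs absent from the GWAS contribute zero to the burden sum rather
  than being dropped-and-renormalized; renormalization would silently change
  the null variance. The count of such SNPs is reported.
* No non-negativity or sum-to-one constraint on GRPs: the summary-statistic
  form has no closed form under constraints, and imputed expression is not
  sign-definite.
* p-values are two-sided normal; Bonferroni is per tissue over its testable
  cell types (sd(F̂_c) > 0). Ranking for "most significant" breaks ties by
  smaller p, then larger |z|, then cell-type name.

## Weight training

Per gene: cis SNPs within 1 Mb of the TSS (boundary inclusive, same
chromosome), MAF > 0.05, covariate-residualized and unit-variance
standardized expression, elastic net with mixing fixed at 0.5. The penalty is
chosen on a 60-point log-spaced path (down to 1e-3 of the maximal penalty) by
10-fold out-of-fold MSE. Reported accuracy is deliberately *nested*:
out-of-fold predictions are produced with the penalty re-selected by an inner
5-fold CV inside each outer training set, so `cv_r2` (squared out-of-fold
Pearson correlation) and `cv_pvalue` (correlation test) carry no winner's
curse over the penalty grid. Predictions of held-out folds omit per-fold
intercepts: the training-fold mean of a globally centered trait is
anti-correlated with the held-out values, and adding it back produces
spuriously significant negative correlations for null genes (we measured
~94% of pure-noise genes "significant" through that leak; with the nested,
intercept-free scheme the null rate at p < 0.05 is ~4%). Final weights are
refit on the full sample at the full-sample CV-selected penalty and stored on
the dosage × standardized-expression scale.

Tissue-level filters: Benjamini–Hochberg over all trained genes' cv_pvalues,
keep q < 0.05; then keep genes with cv_r2 **≥** the median cv_r2 of the
FDR-passing genes (strict ">" would discard exactly half including ties; the
comparison population is configurable). Both flags are stored for every
trained gene.

## Signature curation

Cell types observed in ≤ 50 cells are removed (their mean profiles are too
unstable). Signature genes are selected one-vs-rest per cell type by Wilcoxon
rank-sum or one-way ANOVA with Bonferroni over genes × cell types at
α = 0.05, requiring upregulation in the target type (an optional log2
fold-change threshold is exposed, default 0) and — by default — significance
for exactly one cell type; a flag relaxes the uniqueness rule. MAST is not
reimplemented: it is a full hurdle-model package and out of proportion here.
Selections may be intersected with an imputable-gene universe. The signature
entry is the mean expression over cells of the type. Input normalization
(e.g. log-CPM) and denoising are the caller's responsibility; the module
never re-normalizes.

## The synthetic-study generator

The generator emulates a biobank-scale design end to end; its defaults are
the reference study conditions (10,000 individuals, 600 replicates per
stratum, heritability grid 0.01–0.09, known-signature fractions
0.5/0.7/0.9/1.0, 2,000 SNPs, 100 signature genes, 8 cell types).

* **Genotypes**: two haplotypes per individual, each an AR-1 latent Gaussian
  chain (adjacent-SNP correlation `ld`, default 0.3) thresholded at the
  Φ⁻¹(MAF) quantile, MAF ~ U(0.05, 0.5). This yields diploid dosages with
  geometrically decaying LD — a stand-in for real haplotype structure that
  has no long-range LD, no population stratification and no relatedness, so
  passing tests say nothing about confounding control on real cohorts.
* **Weights and signature**: each gene owns a contiguous cis block and draws
  1–5 causal SNPs with N(0, 1) effects; S = |N(0, 1)| plus a U(2, 4) boost on
  each gene's round-robin marker cell type, redrawn until cond(SᵀS) < 1e4 —
  an LM22-like marker structure with realistic cross-cell-type correlation.
* **Phenotype**: Y = F̂_c* γ + ε with σ²_ε = 1 and
  γ = √(h² σ²_ε / ((1 − h²) var(F̂_c*))), so F̂_c* explains exactly h² of
  trait variance in expectation; h² = 0 is the null.
* **GWAS**: marginal per-SNP OLS (optional covariates + intercept), z = β̂/se.
  A phenotype fully absorbed by covariates yields z = 0 everywhere.
* **Replication**: one panel/weights/signature per study (one biobank
  sample); per replicate, fresh phenotype noise and — for partial-signature
  runs — a fresh random gene mask applied to the *test's* signature while the
  data-generating signature stays complete. Hierarchical seeding
  (`SeedSequence(seed, spawn_key=(stratum, replicate))`) makes every run
  byte-reproducible.

Metrics per stratum: power (causal cell type Bonferroni-significant),
top-selection rate, direction consistency among significant calls, and the
false identification rate over non-causal cell types. The FIR grows with h²
within a tissue because GRPs of different cell types are correlated through
the signature — the motivation for the cross-tissue null below.

### Cross-tissue null design

Two tissues receive independent weights and signatures over disjoint halves
of the SNP range, separated by a 20-SNP guard gap so LD cannot leak across;
the phenotype is driven by a tissue-B GRP and tissue A is tested. With a
single fixed panel, the *realized* in-sample correlation between tissue-A and
tissue-B GRPs adds a fixed per-cell-type offset of typical size √h² to the
null z — independent of sample size — so per-cell rejection rates fluctuate
beyond binomial noise across panel draws while remaining calibrated in
expectation (the offset variance h² and the residual variance 1 − h² sum to
one). The null study therefore redraws the entire study per replicate
(`fresh_genotypes`), making replicates independent Bernoulli draws of the
unconditional level. Calibration of z_c does not depend on n, so the null
study runs at n = 1,500 individuals, 820 SNPs, 40 genes per tissue, 8 cell
types.

### Study sizes used by the test suite and acceptance script

Power/top-rate/direction: n = 5,000 individuals, 2,000 SNPs, 100 genes,
8 cell types, 200 replicates per h² point (tests additionally run the
half-known-signature arm paired on the same replicates). Cross-tissue null:
300–400 fresh replicates per h² ∈ {0.05, 0.1, 0.5}. Summary–individual
agreement: 20 studies at n = 5,000. Weight-training recovery: 55 genes
(15 with 3-of-30 causal cis SNPs at h² = 0.3, 40 pure noise) at n = 2,000.

## Downstream analyses

Trait vectors for correlation are the z-scores of **all** testable cell
types (significant or not); pairs are Pearson-correlated over complete
cases with Bonferroni over pairs, and entries with fewer than 3 shared
observations are left missing, never zero-filled. Tissue-tissue correlation
stacks shared cell types across traits. Gene-to-cell-type assignment is the
argmax of (optionally per-cell-type z-scored) signature expression with
lexicographic, flagged tie-breaks; enrichment of a DE list is an exact
binomial test per cell type (two-sided by default; one-sided by flag — both
enrichment and depletion are reportable) at the cell type's share of the
assignment universe, Bonferroni over cell types.

## Known limitations

* The simulator's genotypes lack stratification, relatedness and realistic
  LD-block structure; type-I control shown here does not certify robustness
  to population structure.
* The test inherits the small-effect approximation; a diagnostic warns when
  |z_p| > 37. Highly correlated cell types within a tissue are flagged by a
  rising false identification rate, not corrected; the permutation-style
  alternative for that regime is not implemented.
* Cross-build GWAS/weight reconciliation is by rsID only; no liftover, no
  INDELs, no imputation-quality filtering.
* Weight training accepts precomputed covariates (genotype PCs, expression
  factors); it does not estimate latent expression factors itself.
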