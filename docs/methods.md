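# Methods

`scqtl` implements a cell-type-resolved eQTL analysis for case/control
single-cell RNA-seq cohorts: pseudo-bulk aggregation, linear-mixed-model
cis-eQTL and genotype-by-disease interaction mapping, joint empirical-Bayes
shrinkage of effects across cell types, sharing/specificity classification,
approximate-Bayes-factor colocalization with GWAS summary statistics, and
distance-matched enrichment testing. This note records the statistical
models, the defaults and why, and the choices made where the design was
genuinely open.

## Pseudo-bulk construction and QC

Donor genotypes (VCF, GT field) are filtered to biallelic SNPs with minor
allele frequency strictly above 0.05 and Hardy-Weinberg exact-test p
strictly above 1e-6, then LD-pruned in sliding windows of 250 variants
(step 50), removing the later member of any pair with r² > 0.9. The HWE
test is the standard exact conditional test on the heterozygote count
(a mid-p variant is available but not the default). Missing genotypes are
imputed to the per-variant mean dosage; multi-allelic records are skipped
with a warning.

Cells with mitochondrial read fraction strictly above 0.20 are removed.
Gene filters run on all post-QC cells study-wide: a gene is kept if
expressed (count > 0) in at least 10% of cells, has mean count at least
0.1, and is not on a supplied exclusion list (mitochondrial and
ribosomal-protein symbols). Counts are normalized by per-cell size factors
— library size over its geometric mean, refined by a pool-and-deconvolve
least-squares step within donor pools of at least 100 cells (pools of
cells ordered by library size are summed, measured against the average
pseudo-cell, and per-cell factors recovered by sparse least squares; this
approximates scran-style deconvolution without claiming exact parity) —
rescaled to mean 1, and transformed as log2(count/sf + 1).

Pseudo-bulk expression is the arithmetic mean of normalized values per
(cell type, donor, gene). Donor/cell-type combinations with fewer than 5
cells are excluded, and a cell type enters eQTL mapping only with at least
40 qualifying donors (both configurable; the bundled demo uses 15 donors
because its simulated cohort is small).

## Mixed-model association scans

Per cell type, donor-level expression is rank-based inverse-normal
transformed, y* = Φ⁻¹((r − 0.5)/n) with average ranks for ties. The top
k = 20 expression PCs (capped at n_donors − 2) are computed from the
transformed matrix.

The null covariance per gene is V = σ²_K·K + σ²_w·diag(1/nCells) + σ²_e·I,
where K is the genomic relationship matrix from standardized filtered
dosages (X_std X_stdᵀ/m) and the 1/nCells weights absorb the varying
precision of donors aggregated from different cell numbers. V is fit once
per gene by REML (Nelder-Mead over the two log variance ratios with the
residual scale profiled out; the OLS boundary is always evaluated, so the
reported optimum never falls below it) and reused for every cis variant of
the gene — the standard single-fit approximation that trades a negligible
loss for an order-of-magnitude speedup.

Each cis variant (within 1 Mb of the gene body, configurable) is tested by
feasible GLS: the model is whitened by the Cholesky factor of the fitted
covariance and an ordinary Wald t-test is read off the whitened design.
Two properties follow by construction: with V ∝ I the scan reduces
*exactly* to OLS, and the residual degrees of freedom can account for
covariates removed upstream. For the additive scan the PCs are regressed
out of expression *and* genotype before testing (the Frisch-Waugh-Lovell
construction; residualizing only the phenotype deflates the statistic
because the genotype's chance correlation with the PC space inflates its
variance), with df = n − 2 − k. For the interaction scan the PCs stay in
the model as fixed effects — disease status correlates with expression
PCs, so regressing them out first would remove disease signal — giving
fixed effects [1, PCs, dose, disease, dose×disease] and a Wald t-test on
the interaction coefficient. Interaction mapping requires at least 10
donors per disease group (configurable down to 5) and drops variants with
MAF ≤ 0.05 in either group among the analyzed donors. PCs collinear with
disease are dropped with a warning.

Wald p-values use the t distribution with the finite-sample df above
rather than a normal; at the cohort sizes simulated here this is what
keeps the null type-I error at its nominal level (verified by the
calibration benchmarks).

## Multivariate shrinkage

Per-cell-type estimates and standard errors for each association are
modeled jointly: b̂_i ~ N(b_i, diag(s_i)·V·diag(s_i)), b_i ~ Σ_{k,l}
π_{k,l} N(0, ω_l U_k) plus a point mass at zero. V is the cross-cell-type
correlation of estimation errors, estimated as the correlation of z-scores
among null-looking associations (max |z| < 2). This matters: pseudo-bulk
cell types share donors, so their errors are positively correlated, and
treating them as independent makes correlated noise look like shared
signal (confidently wrong-signed lfsr in unaffected cell types). Covariance components combine
canonical patterns (identity, one singleton per cell type, all-ones equal
sharing) with data-driven matrices: the strong set (univariate adaptive
shrinkage lfsr < 0.1 in at least one cell type) provides z-scores whose
rank-5 PCA reconstruction and per-PC rank-1 matrices seed extreme
deconvolution — an EM that re-estimates mixture covariances under unit
measurement error, run 50 iterations with eigenvalue flooring at 1e-8 (the
M-step update is a convex combination of PSD terms, so the floor only
guards round-off). Effects are modeled on the effect-size scale (EE); the
scale grid is √2-spaced covering [s_min/10, 2·max|b̂|].

Mixture weights are fit on a random subset (default 10,000 associations,
seed 2023) by EM with a null-biased Dirichlet penalty (pseudo-count 10 on
the null), which resolves the likelihood ridge between the point mass and
vanishing-scale slabs in favor of the null — without it the null weight
never concentrates on truly null data. The EM is accelerated by SQUAREM
steps that fall back to the plain update whenever they would decrease the
penalized objective, so the accepted objective is non-decreasing.
Posteriors are responsibility-weighted mixtures of conjugate MVN
posteriors; the local false sign rate per condition is
min(P(b ≤ 0), P(b ≥ 0)) with the null mass counted in both signs.
Conditions missing an estimate enter with an effectively uninformative
observation (b = 0, large s). Components with negligible fitted weight
(< 1e-8) are skipped in the posterior pass; their responsibility is
assigned to the point mass, which can only push lfsr up (conservative).

## Significance, sharing, classification, pruning

An association qualifies if lfsr ≤ 0.05 in at least one cell type; within
qualifying associations a cell type is significant at lfsr ≤ 0.1 (both
inclusive). The top eQTL per (gene, cell type) is the significant
association with minimal lfsr (ties: larger |posterior beta|, then
lexicographic variant id). Two cell types share a top eQTL if it is
significant in both with same-signed effects whose magnitude ratio is at
least 0.5. Specificity uses the two-cell-type buffer: significant in 1
cell type = unique, in ≥ n_types − 2 = global, otherwise multi (so with 38
cell types, 36 resolves to global). Sign adjustment flips a profile when
the majority sign among significant cell types is negative; exact ties are
left unchanged.

Genes with several top eQTL are pruned to distinct signals: profiles
(non-significant entries zeroed) are compared by Euclidean distance
between centered absolute values; a pair within distance 0.2 keeps the
member significant in more cell types (tie: lower mean lfsr); three or
more profiles are clustered by complete linkage, cutting at the k in 2..5
(capped at m − 1) with maximal mean silhouette width (ties: smallest k),
keeping one representative per cluster. All tie-breaks are deterministic
and pruning is idempotent.

## Colocalization and enrichment

Per SNP and trait, the Wakefield approximate Bayes factor is
log ABF = ½·log(1 − r) + z²r/2 with r = w/(w + se²); prior effect
standard deviations default to 0.15 for the eQTL trait (inverse-normal
scale, sd ≈ 1) and 0.2 for a case/control GWAS on the log-odds scale.
The eQTL side uses mash posterior means and standard deviations in place
of nominal statistics. Hypothesis posteriors PP0–PP4 come from log-sum-exp
sums over causal configurations with priors p1 = p2 = 1e-4, p12 = 1e-5;
the engine agrees with brute-force configuration enumeration to 1e-12.
Variants are harmonized on chrom:pos:ref:alt with allele-swap (beta sign
flip) and strand-flip fallbacks; palindromic A/T and C/G variants are
dropped. Pairs sharing fewer than 100 variable SNPs are skipped with a
reason.

Enrichment uses the two-sided Fisher exact test (Haldane half-count odds
ratio when a cell is zero). Matched null sets are drawn by rejection
sampling with acceptance probability proportional to the ratio of
Gaussian-KDE densities of the target and pool |TSS distance|
distributions, capped at the 99th percentile of the ratio; sampling is
seeded and errors below 1% acceptance. Differential expression for
interaction-eGene overlap is the Wilcoxon rank-sum test per gene (exact
enumeration for tie-free samples of total size ≤ 12, otherwise the
tie-corrected normal approximation), reported with AUC (probability that
the second group exceeds the first), Benjamini-Hochberg adjustment, and a
DE flag at adjusted p < 0.1.

## Synthetic cohorts

The generator emulates a case/control lung cohort at desk scale; its
defaults are 100 donors, 58% diseased, six cell types of unequal
abundance (20–60 cells/donor, some with whole-donor dropout), 20 cis SNPs
per gene. Haplotypes use a copy-with-refresh process: within an LD block
(constant target MAF) each successive allele copies the previous one with
probability equal to the configured correlation, which makes the
adjacent-dosage correlation equal that value in expectation (a thresholded
Gaussian copula attenuates the correlation and was rejected for that
reason). Family members copy whole haplotypes from their founder with
probability equal to the relatedness, so the expected kinship matrix is
block-diagonal with that off-diagonal. Counts are negative binomial
(gamma-Poisson, gene-level dispersion 0.3) around
2^(baseline + β·dose + β_d·disease + β_gd·dose·disease + a), with a
donor random effect a ~ MVN(0, σ²K) on the log2 scale (σ = 0.2) shared
across cell types — so planted effect sizes are in log2-expression units
and pseudo-bulk regression slopes estimate them directly. Mitochondrial
fractions are Beta(2, 25), independent of genotype, present only to
exercise the QC filter. GWAS cohorts are drawn by bootstrap-resampling
panel donors (preserving LD exactly) with a trait loading on a chosen
causal variant at a given per-SNP heritability.

What the generator does *not* emulate — transcriptome-wide co-expression,
doublets, ambient RNA, batch effects, realistic allele-frequency spectra
— bounds what passing benchmarks show: calibration and recovery hold
under the model's own assumptions (NB counts, log-scale additivity,
correctly specified random effects), not necessarily under real-data
violations of them.

## Benchmark problem sizes and expected outcomes

The evaluation module fixes the study conditions: null calibration uses
100 donors and 2,000 null gene-SNP tests per scan; lfsr calibration draws
5,000 associations × 6 cell types from a known four-component prior;
shrinkage benefit uses 20 replicates of 600 associations; specificity
recovery plants |β| = 1 effects (6 genes per pattern plus 36 null genes)
in 100 donors × 6 cell types × 50 cells; interaction recovery plants
β_gd = 1 in 150 donors; colocalization uses 500 individuals per trait on
a 120-SNP panel. On these conditions the scans are calibrated (KS-uniform
p-values; interaction type-I ≈ 0.05), the lfsr is conservative at the
0.05 call level, posterior means beat raw estimates in essentially every
replicate, specificity labels are ≥ 80% correct (errors are almost
entirely multi-pattern effects promoted to global by sharing-induced
significance in one extra cell type), interaction power is near 1 with no
additive-only false flags, and shared/distinct causal configurations are
separated by PP4/PP3 as designed. The numbers themselves are recomputed,
never stored, by the test suite and `scripts/acceptance.py`.

## Known limitations

- The EMMAX-style single null fit per gene slightly misstates per-SNP
  standard errors when a variant explains a large variance share.
- Extreme deconvolution runs on strong-set z-scores with unit errors, an
  approximation to running it on effect estimates with their standard
  errors.
- The deconvolution size factors are a least-squares approximation, not
  the reference pooling schedule.
- Conditions absent from an association are approximated by an
  uninformative pseudo-observation rather than exact marginalization.
- No permutation-based gene-level p-values, trans-eQTL, conditional
  multi-signal mapping, or LD-aware (SuSiE-style) colocalization.
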