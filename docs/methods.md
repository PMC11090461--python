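# Methods

## Prediction models

### RR-BLUP / single-component REML

All single-random-component models — RR-BLUP on markers, RR-BLUP on ASVs,
and genotype-level G-BLUP — are fit as

    y = X b + Z u + e,   u ~ N(0, K σ²_u),   e ~ N(0, σ²_e I)

with K the identity (RR-BLUP) or the additive relationship matrix (G-BLUP).
REML is profiled on the variance ratio λ = σ²_u/σ²_e via a spectral
decomposition of Z K Zᵀ restricted to the orthogonal complement of the fixed
effects (the classic one-dimensional mixed-model trick), optimized on
log₁₀ λ over [−10, 10] with a bounded scalar search at tolerance 1e-8. When
the restricted likelihood is maximized at the lower boundary the component
is reported as exactly zero and the fit reduces to ordinary least squares.
Rank-deficient fixed designs are reduced to a full-rank column basis by
pivoted QR, with the aliased columns logged.

### The joint SNP+ASV model

The two-component predictor uses **plug-in** variances, mirroring the
estimation strategy it implements:

1. σ²_α and σ²_ε from the SNP-only RR-BLUP REML fit (design factors fixed);
2. σ²_γ from an ASV-only RR-BLUP REML fit with design factors plus the first
   three genotype principal components fixed, so population structure is not
   attributed to the microbiome;
3. Henderson's equations solved at those values. With columns ≫ rows the
   n×n kernel system V = σ²_α ZZᵀ + σ²_γ MMᵀ + σ²_ε I is solved by Cholesky
   factorization; with few columns the column-side normal equations are used.
   The two routes agree to 1e-8 and equal generalized ridge regression with
   per-block penalties σ²_ε/σ²_α and σ²_ε/σ²_γ (tested against the dense
   closed form).

The residual variance carried into the joint fit is the SNP-only estimate.
A joint two-component REML would avoid the slight double-counting this
implies, but the plug-in scheme is the method under study; the residual
choice is logged in the fit metadata. Fixed factors are dummy-coded with the
first level as reference and an always-present intercept; SNP dosages are
mean-imputed and column-centered, ASV matrices column-centered, both on the
full panel (no phenotype is involved, so this leaks nothing into
cross-validation).

### Cross-validation and comparisons

Folds are genotype-disjoint: genotypes are partitioned into k≈equal groups
and every plot inherits its genotype's fold, so the model never sees a test
genotype during training. Variance components are re-estimated inside every
training fold (no leakage); accuracy is the Pearson correlation of predicted
and observed phenotype over held-out plots. Repeats differ only in the
fold-assignment seed. The shuffled-microbiome control arm reuses the same
folds (paired design) with ASV rows permuted uniformly within nitrogen
treatment once per repeat — permutation preserves each treatment's row
multiset exactly and destroys genotype alignment while keeping the column
count and marginal distributions.

Arms are compared with a paired two-sided t-test on (repeat, fold) accuracy
pairs (Wilcoxon signed-rank available), with the conventional star ladder at
0.05/0.01/0.001/0.0001. One behaviour worth knowing: when the microbiome
carries no signal, the ASV-only REML occasionally estimates a small positive
σ²_γ, and the resulting noise covariates cost a tiny but *systematic*
out-of-fold accuracy — a paired test over many correlated fold pairs will
flag that degradation far more often than the nominal rate. Directional
claims ("the microbiome arm improves accuracy") are therefore the meaningful
ones; the package's own null-control checks count significant
*improvements*, which are controlled at the nominal level.

## Mediation scan

Per ASV j the mediator model M_j = Q A_j + Z B_j + e_j and, once, the
outcome model y = Q v + Z a + M c + e, where Q is the confounder matrix
(intercept, 3 genotype PCs, treatment, block, split plot, split-plot block
dummies; 11 columns at the full design cardinalities). A_j and v are GLS
estimates; B_j, a and c are ridge-shrunk random-effect BLUPs with the same
plug-in variance recipe as the prediction model.

Path tests:

* **genetic path** — score statistic T = rᵀGr / rᵀr with r the
  Q-residualized abundance and G = ZZᵀ, against within-treatment row
  permutations of the abundance (equivalent to permuting genotype labels
  while keeping the treatment-aware confounder projection fixed);
* **phenotype path** — |c_j| against the same within-treatment permutations
  of M's rows, re-solving the outcome model per permutation with the plug-in
  variances held fixed.

Raw per-ASV permutation p-values are floored at 1/(B+1), which is too coarse
for Benjamini–Hochberg screening of a few true mediators among hundreds of
ASVs (the BH threshold k·q/m sits below the floor). Each ASV's statistic is
therefore studentized against its own permutation null and the studentized
null draws are pooled across ASVs, giving a floor of 1/(m·B+1); this is the
standard pooling device used in large-scale permutation scans and is exact
under exchangeability of the studentized statistics. The joint p-value is
max(p_genetic, p_phenotype) — the joint-significance (MaxP) rule, which is
conservative under either single-path null — screened at BH FDR 0.05.
Mediator-model REML shares one spectral basis across all ASVs (Q and Z are
common), so the per-ASV cost is a rotation plus a scalar optimization.

## Synthetic hologenome generator

The generator emulates the split-plot field trial the models assume:

* **genotypes** — two independent haplotypes per individual, each a
  thresholded Gaussian with equicorrelation ρ=0.9 inside LD blocks of
  `ld_block_size` adjacent markers (independent across blocks), MAF drawn
  uniformly from `maf_range`; markers laid on a synthetic grid (100 bp
  spacing, blocks never straddling chromosomes). Defaults target the field
  scale: 230 genotypes; tests and examples use smaller panels.
* **design** — every genotype once per (treatment × block) cell (2×2),
  random field order cut into 4 contiguous split plots of 3 split-plot
  blocks; quadrant = (block, split plot). Plots drop out i.i.d. at rate
  125/920 ≈ 0.136, reproducing ~795 retained plots of 920 at field scale.
  The real trial's missingness mechanism is unknown; i.i.d. dropout is the
  neutral choice.
* **microbiome** — ASV log abundances = intercept (N(−8,1), the scale of log
  relative abundances) + treatment effect (sd 0.3) + block/split-plot
  effects (sd 0.1) + unit noise; heritable ASVs additionally get a sparse
  5-SNP genetic component rescaled so the genotype-attributable variance
  fraction equals `asv_h2`. Abundances are generated directly on the log
  scale — no compositional renormalization — matching the scale the models
  consume. Taxonomy is assigned round-robin (groups nest in classes), with a
  field-scale preset of 3626 ASVs / 154 groups / 19 classes.
* **phenotype** — mean + design fixed effects + polygenic SNP component +
  sparse ASV component + noise, with the three random components rescaled so
  realized variance shares equal `h2_snp`, `var_share_asv` and the
  complement exactly. Causal ASV effects have random sign and magnitude
  uniform in [0.8, 1.2] before rescaling, so every planted effect is bounded
  away from zero. With `treatment_specific`, ASV effects act only in LN.
  Mediators are exactly the ASVs with both a genetic and a phenotype path;
  heritable-but-neutral and causal-but-non-heritable ASVs are planted as
  negative controls.

What the generator does **not** emulate: sequencing counts and
compositionality (library-size effects, zero inflation), spatial
autocorrelation beyond the split-plot factors, genotype-by-microbiome
interaction, and temporal drift of the microbiome. Passing tests therefore
demonstrate correctness of the estimation machinery under the assumed model,
not robustness to those real-data features.

## Scenario sizes and numerical choices

The statistical acceptance checks run at reduced scale, chosen once: the CV
scenarios use 100 genotypes × 1000 SNPs × 100 ASVs (~345 plots) with
h²_snp = 0.4 and ASV share 0.2 (0 for the null, which also sets asv_h2 = 0 —
with heritable ASVs retained, the microbiome legitimately proxies genotype
and the arms genuinely differ, so the *global* null is the coherent type-I
scenario); the mediation power scenario uses 200 genotypes (~700 plots,
near the field trial's 795) × 600 SNPs × 150 ASVs with 10 planted mediators
(asv_h2 = 0.5, ASV share 0.3) and 200 permutations; the null-FDR scenario 80
genotypes × 80 ASVs over 50 datasets. Five-fold CV with 3 repeats is used
throughout the checks (the field analysis convention is 20 repeats, which
the API defaults to).

Other numerics: GRM is VanRaden method 1 on mean-imputed dosages, excluding
monomorphic markers; PCA fixes signs so each component's largest-magnitude
loading is positive; LD pruning slides a 10 kb window in 10 bp steps and
removes the later marker of any pair with r² > 0.1, treating r² against a
monomorphic marker as 0; tie-breaks in top-fraction selection are by feature
id; undefined quantities (zero-baseline improvement, constant-fold accuracy,
constant-input correlations) are reported as missing rather than guessed.

## Known limitations

* The plug-in variance scheme slightly over-shrinks when a spurious ASV
  variance is estimated under the null (see above); a joint REML flag would
  trade fidelity to the method under study for calibration.
* The mediation estimator is a transparent two-stage ridge with
  permutation-calibrated joint significance; the original high-dimensional
  mediation estimator it stands in for is not restated in the source
  material, so exact parity with its calls is not claimed.
* Permutation tests assume exchangeability within treatment; spatially
  structured residuals would violate this.
* The generator's exact variance-share rescaling removes sampling
  variability in the planted shares; recovery tests measure estimator error
  only.
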