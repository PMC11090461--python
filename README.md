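# megs — microbiome-enabled genomic selection

`megs` implements genomic prediction that treats a host's root-associated
microbiome as a second source of predictive signal alongside its genome. The
motivating setting is a maize diversity panel phenotyped under high- and
low-nitrogen (HN/LN) field conditions, where rhizosphere amplicon sequence
variants (ASVs) are partly heritable and partly shaped by the
microenvironment — so the package couples the prediction models with
shuffled-microbiome null controls and a mediation scan that asks which
microbes actually sit on the genotype → microbe → phenotype path.

## The models

**MEGS prediction model.** For plot-level phenotype *y* with nitrogen
treatment *f*, block *b*, split plot *sp* and split-plot block *spb* as fixed
effects:

```
y_ijkuv = μ + f_i + b_j + sp_u + spb_v + Σ_l α_l g_kl + Σ_t γ_t m_ijkt + ε
α_l ~ iid N(0, σ²_α),   γ_t ~ iid N(0, σ²_γ),   ε ~ iid N(0, σ²_ε)
```

where `g_kl` are centered SNP dosages and `m_ijkt` are log relative ASV
abundances. Variance components are **plug-ins**: σ²_α comes from an
RR-BLUP fit of SNPs alone, σ²_γ from an RR-BLUP fit of ASVs alone with the
first three genotype principal components as fixed covariates, and the joint
model is then solved through Henderson's mixed-model equations (equivalently,
generalized ridge with per-block penalties σ²_ε/σ²_α and σ²_ε/σ²_γ).
Accuracy is assessed by repeated five-fold cross-validation with
genotype-disjoint folds, against a control arm in which microbiome rows are
permuted within nitrogen treatment.

**Conventional G-BLUP.** Genotype effects `g ~ MVN(0, A σ²_g)` with the
VanRaden additive relationship matrix `A`, optionally augmented with
taxonomic-group abundances as a second random component.

**Mediation scan.** Per ASV *j*, a mediator model `M_j = Q A_j + Z B_j + e_j`
and one outcome model `y = Q v + Z a + M c + e`, with Q the confounder matrix
(3 genotype PCs + design factors). The genetic path is tested with a
permutation-calibrated variance-component score statistic, the phenotype
path with the permutation null of the shrunken coefficient |c_j|; an ASV is
called a mediator by the joint-significance (MaxP) rule at
Benjamini–Hochberg FDR.

A synthetic hologenome generator (`megs.synthetic_data`) produces
genotype → microbiome → phenotype datasets with the split-plot HN/LN layout,
configurable heritability shares, LN-only microbiome effects, and a
ground-truth ledger for recovery tests.

## Worked example

```python
from megs import SimulationConfig, simulate_dataset
from megs.evaluation import PredictionData, cross_validate, compare_models, relative_improvement

cfg = SimulationConfig(n_genotypes=100, n_snps=1000, n_asvs=100,
                       n_groups=12, n_classes=5, ld_block_size=5,
                       n_causal_asvs=15, n_mediators=5,
                       h2_snp=0.4, var_share_asv=0.2, seed=1)
ds = simulate_dataset(cfg)                      # ~345 plots, HN/LN x 2 blocks
data = PredictionData.from_simulated(ds)
cv = cross_validate(data, arms=("snp", "snp+asv"), k=5, n_repeats=3, seed=1)
r_snp, r_megs = cv.mean_accuracy("snp"), cv.mean_accuracy("snp+asv")
stat, p, star = compare_models(cv, arm_a="snp+asv", arm_b="snp")
print(f"SNP-only  accuracy: {r_snp:.3f}")
print(f"SNP+ASV   accuracy: {r_megs:.3f}")
print(f"relative improvement: {100*relative_improvement(r_megs, r_snp):.1f}%  (p={p:.2g} {star})")
```

Output:

```
SNP-only  accuracy: 0.349
SNP+ASV   accuracy: 0.447
relative improvement: 28.1%  (p=1.3e-07 ****)
```

With 20% of phenotypic variance planted on ASVs, the joint model recovers a
large, highly significant accuracy gain over SNP-only prediction; on null
data (no microbiome signal) the same comparison comes out non-significant.

The same workflow is available from the shell:

```bash
megs simulate --out sim/ --seed 1
megs cv --data-dir sim/ --arms snp,snp+asv --repeats 5 --out cv.csv
megs mediate --data-dir sim/ --permutations 200 --out mediation.tsv
megs run --out run/ --seed 1          # full pipeline with manifest
```

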