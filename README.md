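# gstk — a scriptable genomic selection pipeline for plant breeding

`gstk` implements the full genomic prediction and selection workflow a
small-to-medium plant breeding program runs every advancement season,
as a Python library plus a `gstk` command line:

1. **Genotype preparation** — load biallelic SNPs from VCF into a
   taxa × sites dosage matrix; filter sites on minor-allele frequency and
   missingness and taxa on missingness; lift low-density (LD) progeny
   assays onto a high-density (HD) parental marker set.
2. **Data processing** — impute scattered missing scores by LD-KNN
   (k nearest taxa over the sites in highest linkage disequilibrium with
   the target site) or numeric KNN; merge genotypes with per-environment
   BLUE phenotype tables; summarize daily weather series into an
   environments × covariates matrix and an enviromic kinship Ω.
3. **Training-set optimization and cross-validation** — pick an optimal
   training subset by genetic-algorithm search over PEVMean / PEVMax /
   CDMean criteria; assess models under CV0 / CV00 / CV1 / CV2 /
   leave-one-factor-out masking schemes.
4. **Genomic prediction** — single-trait G-BLUP with REML variance
   estimation (plus an EM ridge variant), multivariate kernel G-BLUP for
   correlated traits, and Bayesian reaction-norm models for
   multi-environment trials.

## The models

Single-trait G-BLUP:  y = Xb + Zu + e,  u ~ N(0, σ²ᵤK),  e ~ N(0, σ²ₑI),
with K the VanRaden kinship ZZ′/(2Σpⱼ(1−pⱼ)) or a Gaussian kernel on
marker distances. REML profiles the restricted likelihood over
λ = σ²ₑ/σ²ᵤ on one spectral decomposition; prediction error variances and
reliabilities rᵢ² = 1 − PEVᵢ/(σ²ᵤKᵢᵢ) come from the solution at λ̂.

Multi-environment reaction norms: with Z_g, Z_e the record→strain and
record→env incidences, environment enters as a fixed factor and the
random structure is assembled from G = Z_gKZ_g′, the Hadamard products
G∘(Z_eZ_e′) (G×E, common variance), per-environment masked copies
(environment-specific variances), W = Z_eΩZ_e′, and G∘W — the nine
formula tags from `G+E` up to `G+E+GxE_i+W+GxW_i`. Inference is a Gibbs
sampler that diagonalizes each kernel once and draws variance components
from scaled-inverse-χ² full conditionals (default chain 10,000 / 2,000
burn-in / thin 5 → 1,600 retained draws).

Multi-trait: Y = 1μ′ + U + E with U ~ MN(0, K, Σ_g), E ~ MN(0, I, Σ_e)
and inverse-Wishart updates on Σ_g, Σ_e; unobserved trait cells are
sampled inside the chain, which is what lets CV2-style prediction borrow
a correlated secondary trait observed on the selection candidates.

## Worked example

Everything runs on synthetic data produced by the built-in generator
(biparental families with controlled heritability and G×E, trial
locations with daily weather):

```bash
gstk simulate --out fixture --seed 1 --families 5 --lines-per-family 6 \
    --chromosomes 2 --markers-per-chrom 40 --envs 3
gstk cv --vcf fixture/genotypes.vcf --pheno fixture/pheno.csv --trait trait1 \
    --scheme cv1 --k 3 --niter 300 --burnin 100 --thin 2 --seed 1 --out cv.csv
```

prints

```
fixture written to fixture (30 lines x 80 markers)
CV1: mean PA 0.793 (SE 0.021, range 0.752..0.823) -> cv.csv
```

Mean PA is the Pearson correlation between observed and predicted BLUEs
on masked strains, averaged over the three folds, with its standard
error and range — i.e., how well the model predicts lines it has never
seen phenotypes for. The same stages run from one YAML config:

```bash
gstk run --config pipeline.yaml   # 4 stages, resumable manifest
```

In Python, the same CV1 experiment is:

```python
from gstk import (read_vcf, load_pheno, merge_geno_pheno, genomic_kernel,
                  make_partitions, run_cv, MEModelSpec, GibbsConfig)
from gstk.cross_validation import me_model_fitter

ds = merge_geno_pheno(read_vcf("fixture/genotypes.vcf"),
                      load_pheno("fixture/pheno.csv"), "trait1")
k = genomic_kernel(ds.geno, "linear")
plan = make_partitions(ds, "CV1", k=3, seed=1)
fitter = me_model_fitter(MEModelSpec("G+E"), k, None,
                         GibbsConfig(n_iter=300, burn_in=100, thin=2, seed=1))
print(run_cv(ds, fitter, plan).summary())
```

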