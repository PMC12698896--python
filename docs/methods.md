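# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Genotype representation and QC

Genotypes are ALT-allele dosages 0/1/2 over biallelic SNPs; a missing or
half-missing call is a dedicated sentinel (−1) that never enters
arithmetic (numeric consumers receive NaN). Phase is discarded
("0|1" ≡ "0/1") because every downstream stage is dosage-based. Site
filters act on minor-allele frequency (computed over non-missing calls
only, so MAF ∈ [0, 0.5] by construction) and per-site missingness; taxa
filter on per-taxon missingness. The pipeline default order is sites
first, then taxa; both thresholds default to 0.2 missingness and
MAF ≥ 0.05 — common preliminary-yield-trial settings, configurable and
echoed into every run log.

The PC integrity check guards marker-platform transitions (e.g. an assay
panel before and after imputation to a denser set): both matrices are
restricted to shared taxa, mean-imputed, column-centered, and
SVD-decomposed; the statistic is the absolute Pearson correlation of
taxa scores on matched leading PCs. Values near 1 mean relative genetic
distances survived the processing.

## Imputation

**LD-KNNi.** For a missing cell (taxon *t*, site *s*): candidate sites
within `max_dist_bp` of *s* on the same chromosome (default 10 Mb; 0 =
unbounded) are ranked by squared Pearson correlation with *s* over
pairwise-complete taxa; the fingerprint is the top `l_sites` (default
30) of those at which *t* itself is called — a site where the target is
missing carries no distance information, and without this restriction a
sparsely genotyped taxon (the LD-panel case) would be measured on an
unusable fingerprint. Donor distance is 1 − IBS over the fingerprint
with het-vs-hom counting half; the imputed dosage is the 1/(d+1e−9)
weighted mean of the `k_neighbors` (default 5) nearest called donors,
rounded into {0,1,2}. Ties break toward the lowest taxon index, making
the procedure fully deterministic. Cells with no usable donor fall back
to the rounded site mean and are counted in the report, so the output
never contains missing cells.

**Numeric KNN.** Taxa distances are Euclidean over mutually called
sites, scaled by the number of compared sites; the imputed value is the
plain (or inverse-distance-weighted) mean of the k nearest called
donors. Real-valued imputations are preserved in the report; the stored
matrix is rounded.

**LD→HD.** The low-density target panel is merged with the high-density
reference on marker IDs (ref/alt-swapped sites have dosages flipped
2↔0; irreconcilable allele pairs are dropped to missing), target taxa
receive MISSING at HD-only sites, and LD-KNNi runs over the merged
matrix; reference rows pass through untouched. An intersection below
50% of the LD sites raises an error pointing at marker-name
reconciliation. This preserves the pipeline stage functionally without
haplotype phasing; pedigree-aware phasing methods are expected to beat
it when parent-offspring links are known, and no claim is made
otherwise.

## Phenotypes

The pipeline is two-stage: model training consumes per-environment
BLUEs. For completeness a single-location fixed-effects fit
`value ~ strain + trial + block-in-trial (+ covariate)` is provided via
statsmodels OLS with treatment coding; only strain contrasts are
meaningful, and the anchor (first strain level as reference) is
documented rather than configurable because any constant-shift
convention yields the same predictions downstream. A rank check precedes
the fit so confounded layouts fail loudly instead of silently pinning
coefficients.

Merging intersects strain identifiers (optionally after trim/casefold
normalization, logged), drops records lacking the focal trait, and
reports every removal count.

## Enviromics

Daily weather series per trial location (the standard satellite-derived
covariate set: temperature, dewpoint, long/short-wave and PAR radiation,
precipitation, wind, relative humidity, evapotranspiration — 14 unique
covariates) are summarized over the growth window by the mean (sum
available per covariate, e.g. for precipitation), z-standardized across
environments, and turned into an environmental kinship: linear
Ω = WW′/q, or Gaussian Ω = exp(−θ·d²/median(d²)) with the median
heuristic making θ a unitless multiplier (default 1). The tested data
path is an offline cache table (env_id, date, covariate, value); a live
database fetch can be supplied as a callable but no network code ships.
Gap handling is explicit: gaps are reported at load and are an error at
summarization unless skipped.

## Kernels and multi-environment structure

The genomic kernel is VanRaden kinship K = ZZ′/(2Σp̂ⱼ(1−p̂ⱼ)) (columns
centered at 2p̂ⱼ) or Gaussian with the same median-heuristic bandwidth
as the environmental kernel. For a near-inbred panel the VanRaden
diagonal averages ≈ 2 (≈ 1+F); heritabilities are therefore always
reported on the phenotypic-variance scale, weighting each variance
component by its kernel's mean diagonal — without this, a perfect fit
on an inbred panel would report h² ≈ h²/(2−h²).

Record-level model terms over n strain-environment records, with Z_g and
Z_e the strain and environment incidences: G-main = Z_gKZ_g′; G×E with a
common variance is the Hadamard product with the same-environment block
indicator; environment-specific deviations are the G-main term masked
(rows/columns zeroed) per environment, keeping all terms on one record
dimension so a single solver interface serves every formula; W-main =
Z_eΩZ_e′ is a *random* term with its own variance (the environment
factor E itself is always fixed, intercept + drop-first coding); G×W and
its per-environment masked version complete the set. Nine formula tags
are accepted (`G+E` … `G+E+GxE_i+W+GxW_i`); Hadamard products and
principal-block masking of PSD matrices are PSD, which the tests assert
at −1e−8 on the minimum eigenvalue.

## Single-trait inference

REML profiles the restricted likelihood over λ = σ²ₑ/σ²ᵤ on the spectrum
of S(ZKZ′)S (S the projector off the fixed design), computed once;
the 1-D search is bounded in [1e−6, 1e6] on the log scale, and a
boundary optimum is reported with a warning rather than hidden. BLUPs
extend over the full kernel, so strains without records are predicted by
kinship regression automatically; PEV comes from the shrinkage of the
full-kernel covariance, reliability is 1 − PEV/(σ²ᵤKᵢᵢ) clipped to
[0,1]. A dense Henderson-equation solver is kept as an independent
cross-check and jitters K⁻¹ only when the kernel is numerically
singular (the VanRaden kernel always is — centering puts the ones
vector in its null space).

The EM ridge variant runs in the dual (n×n) spectral form so that
m ≫ n panels remain well-posed as the residual variance shrinks; its
fixed point is self-consistent with the direct ridge solution at
λ = σ²ₑ/σ²_b, which is tested.

## Bayesian kernel samplers

Each covariance term is eigendecomposed once (eigenvalues below 1e−10 of
the maximum truncated; rank recorded) and its random effect updated in
the rotated basis, where the full conditional is diagonal. Variances get
scaled-inverse-χ² full conditionals with df₀ = 5 and scales set so the
prior mode allocates R² = 0.5 of var(y) equally among the random terms
(divided by each kernel's mean diagonal); fixed effects have a flat
prior. Held-out records are handled by data augmentation — their y is
resampled from the model each sweep — so parameter draws marginally
follow the posterior given observed records only while sampled effects
remain defined over the full kernel support. For environments absent
from training, the fixed-effect design row is the average of the
training environment rows (effect = mean of training env effects); a
formula without enviromic terms refuses such predictions unless the
caller explicitly accepts genotype-main-effect extrapolation.

One property of this machinery is worth stating because it shapes an
expected test outcome: the posterior *mean* of a variance component
whose true value is zero does not reach zero. The weakly identified
eigendirections of a rank-n kernel keep a positive floor (observed at
roughly 0.1–0.2 of the genetic variance for the common-deviation G×E
term at 1,400 records; the package's own validation on data generated
exactly from the model shows the same floor while recovering non-zero
components accurately). A REML point estimate collapses to the boundary
instead; users comparing the two should expect that difference.

The multi-trait sampler rotates through the kernel eigenbasis, samples
the T×T trait-covariance matrices from inverse-Wishart full
conditionals, and resamples unobserved trait cells from their
conditional normals given the observed traits of the same record
(grouped by missingness pattern, one Cholesky per pattern per sweep).
The marker-effect Bayesian ridge variant is fit in its exact kernel-dual
form (linear marker kernel); marker effects themselves are not exposed.

Chains are fully determined by the configuration seed. Defaults are
10,000 iterations, 2,000 burn-in, thinning 5 (1,600 retained draws);
experiments in the test suite use shorter chains, stated inline, chosen
by inspecting effective-sample counts on the variance components.

## Cross-validation

CV2 masks random records stratified by environment; CV1 masks whole
strains; CV0 masks whole environments; CV00 crosses environment folds
with strain folds and evaluates only masked-strain × masked-env cells;
LOFO masks one level of any factor column (leave-one-trial-out when the
factor is the trial). Predictive ability is the Pearson correlation on
masked records computed within each left-out unit — the fold for
kfold/CV1, the environment within fold for CV2, the level for CV0/LOFO,
the cell-set for CV00 — and the summary reports mean, standard error
over units, and range, the same shape as a model-comparison table.
Units with fewer than 3 evaluable records are flagged and excluded from
the summary. Leakage (a masked strain or environment contributing to its
own training set) is asserted in tests, not assumed. Model comparisons
run on the identical plan so partition noise cancels.

## Training-set optimization

Criteria derive from the mixed-model equations of y_T = 1μ + u_T + e
over all candidates with σ²ᵤ = 1, σ²ₑ = λ (default λ = 1, i.e. h² = 0.5,
exposed as a flag): PEVMean/PEVMax minimize the mean/max prediction
error variance of the targets (default: all non-training candidates);
CDMean maximizes mean(1 − PEVᵢ/Kᵢᵢ). A singular kernel gets a 1e−8
ridge jitter with a warning. The genetic algorithm keeps an elite,
crosses parents by union-subsampling, mutates by member swaps, and stops
on generation or stall limits (defaults 100/5/0.05/200/50); elitism
makes the best-so-far trace monotone. The 12-choose-5 instance is small
enough that tests compare every subset against an independent
GLS-conditioning oracle and check the GA finds the global optimum.

## The synthetic-data generator

The generator emulates a public soybean-style program: inbred founders
with block-copy LD along chromosomes, biparental families, per-line
mosaic genomes with Poisson crossovers (map expansion ×2 for repeated
selfing; interference ignored), residual heterozygosity ~2%, uniform
marker spacing at 1 Morgan per chromosome. Defaults: 10 families × 20
lines, 5 chromosomes × 200 markers, 7 environments with the 14-covariate
daily weather set over a May 1 – Nov 30 season. Phenotypes are additive:
100 QTL sampled from the marker set, main genetic values scaled to
variance 1; multi-trait effects drawn with a target genetic correlation
that is re-imposed exactly on the realized breeding values (finite QTL
counts otherwise let the sample correlation drift by ±0.1 or more, which
would contaminate correlation-recovery experiments); G×E enters as
environment-covariate-driven rescaling of QTL effects scaled to the
requested variance ratio; residual variance is solved per trait so
var(TBV)/var(y − env mean) hits the target h². All generators are pure
functions of config + seed.

What it does not emulate — selection history, population structure
beyond family clustering, genotyping error, assay-specific missingness
patterns, spatial field trends, covariate measurement error — bounds
what passing tests show: they certify the estimators against their own
generative assumptions at desk scale, not performance on any real
breeding panel.

Problem sizes in the test suite and acceptance script (500 lines × 1,000
markers for heritability recovery; 400 records × 10 replicates for the
G×E model contrast; 1,400 records for the null-G×E check; 200 × 1,000 at
20% masking for imputation; 300 lines × 10 replicates for multi-trait
borrowing) were chosen as the smallest instances at which the quantities
of interest are stable across seeds.

## Known limitations

- LD→HD imputation is population-based only; no phasing, no pedigree.
- The W main effect competes with the fixed environment factor for
  between-environment variance; with few environments its variance is
  weakly identified.
- Environment-specific-variance formulae (the `_i` tags) estimate one
  variance per environment and degrade when per-environment data are
  thin — the expected behavior, visible in cross-validation.
- No spatial adjustment, no dominance/epistasis kernels, no
  covariate feature selection for the enviromic kernel.
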