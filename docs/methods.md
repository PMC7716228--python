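# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `mtgp`.

## Phenotype-stage mixed models

The BLUE model treats genotype as fixed and environment, block nested in
environment, and genotype × environment as independent Gaussian random
effects.  Variance components are estimated by REML: the residual variance
is profiled out, the remaining variance *ratios* are optimized on the log
scale (L-BFGS-B, bounds e±12) through a Cholesky factorization of
H = I + Σ γ_r Z_r Z_r′, and fixed effects follow by GLS.  Genotype one-hot
columns absorb the intercept, which keeps the fixed design full-rank
without reference-level bookkeeping.  Per-environment adjusted means are
assembled as genotype effect + environment BLUP + G×E BLUP
(`scope="per_env"`); `scope="overall"` returns the across-environment
genotype effect alone.  Standard errors come from the GLS covariance of the
genotype effects; BLUP prediction error is not propagated into them.

Broad-sense heritability uses the per-environment model with genotype and
block random, H² = σ²G/(σ²G + σ²e).  In an augmented design the repeated
checks are the only replicated genotypes, so σ²G is identified but noisy;
the estimator can land well below or above the generating value in a single
small environment (the tests budget ±0.25 for an 83-line panel and ±0.08
for 200 genotypes × 3 replicates).  The coefficient of variation is
reported as 100·σe/mean.  The days-to-heading covariate enters centered, as
a plot-level fixed effect.

An independent cross-check: on a shared small dataset the REML variance
components agree with lme4 (fitted through Rscript) to 2 % relative
tolerance.

## Genotype QC

Filter chain, applied in order with strict inequalities for removal:
line missingness > 0.85, marker missingness > 0.5, MAF < 0.05 (computed
over observed calls), heterozygous-call frequency > 0.10.  The
heterozygosity rule removes *high*-heterozygosity markers: in an inbred
wheat panel residual heterozygosity above ~10 % indicates paralogy or
miscalls rather than true segregation.  The per-site allelic test builds
the 2×2 table of lines carrying / not carrying each allele (heterozygotes
count toward both) and keeps a SNP when Fisher's exact test rejects
independence at α = 0.001; a monomorphic site is an error.  Imputation is
per-marker mean dosage (rounded variant available) — a deliberately simple
stand-in whose accuracy is validated against masked truth rather than an
LD-aware method.  The genomic relationship matrix is G = XX′/p with columns
centered and scaled by the sample (n−1) standard deviation.

## Bayesian prediction models

**MGBLUP.**  With cells ordered line-within-environment, the genetic kernel
is J_I ⊗ G and the reaction-norm G×E kernel is I_I ⊗ G, so after one
eigendecomposition G = VΛV′ every Gibbs update is a set of independent
scalar draws.  Priors: flat on environment means; scaled-inverse-χ²
(df = 5, scale = 0.5 × phenotypic variance) on σ²G, σ²GE, σ²e.

**BMTME.**  Y = Xβ + Z₁b₁ + Z₂b₂ + E with b₁ ~ MN(0, G, Σt),
b₂ ~ MN(0, Σ_E ⊗ G, Σt), residual rows iid N(0, R_e).  All full
conditionals are conjugate; rotating rows by the eigenvectors of G (and of
Σ_E for b₂) makes the effect updates row-independent L×L solves, batched
with stacked Cholesky factorizations.  Priors are inverse-Wishart
(ν = dim + 2, identity scale) on Σt, Σ_E, R_e and flat on β.  Numerically
non-positive-definite inverse-Wishart draws are retried with an escalating
jitter on the scale matrix; the retry count is reported on the fit.
Trait/environment genetic correlations are posterior means of the
*per-draw* correlation matrices of Σt and Σ_E.

Missing or masked response cells are handled by data augmentation (sampled
from the residual conditional each sweep), which gives cross-validation and
leave-one-environment-out prediction a single code path and keeps all
crossproducts rotation-diagonal.  Two consequences worth knowing:

- Mixing for cells with *no* information (a line masked everywhere under an
  uninformative kinship) is slow — the augmented value and the line effect
  form a nearly unit-root pair — so posterior means for such cells need
  longer chains (the no-information tests run 4,000 sweeps).
- σ²e / R_e conditionals include augmented residuals, as required for a
  correct sampler on the augmented joint.

**Identifiability.**  With one observation per line × environment cell, the
cell-level b₂ is separated from the residual only through the off-diagonal
structure of G.  The trait correlation of Σt (shared by b₁ and b₂) is well
recovered in structured panels (±0.15 at 200 lines); the split between the
b₁ variance and the off-diagonals of Σ_E is weakly identified, so
environment-correlation estimates carry substantially more posterior spread
and can shift sign in small panels.  This is a property of the model, not
of the sampler.

**BMORS.**  Stage one fits MGBLUP per trait under the same mask; stage two
regresses the target trait on all L stage-one predictions, standardized
with training-cell means and standard deviations that are reused unchanged
on validation cells.  The stage-two sampler is a small conjugate Gibbs
ridge with a nearly flat prior (τ² = 10⁴).  Note that the target's own
stage-one prediction is one of the regressors, so its coefficient is large
by construction whenever the target has signal — the null-coefficient
property applies to the *other* traits.

**MCMC defaults** are 15,000 iterations with 10,000 burn-in and no
thinning, overridable everywhere; tests and the acceptance script use
600–3,000 iterations, which the parameter-recovery checks show is
sufficient at desk scale.

## Neural models

SMDL/MMDL are dense feed-forward networks implemented in NumPy: three
hidden layers of equal width, ReLU, inverted dropout (default 0.25) after
each hidden layer, linear outputs (1 or L), mean-squared-error loss,
Adam (default learning rate 10⁻³, batch 32), He initialization.  Inputs
are the standardized marker dosages concatenated with one-hot environment
indicators; responses are standardized per trait and predictions
de-standardized, making training invariant to affine response changes.
Training is deterministic given the seed on a single thread.

Hyperparameter tuning follows a full-factorial response-surface search
(neurons 5–70 step 5 × epochs 10–80 step 10 = 112 cells) scored by
cross-validated Pearson correlation; at each epoch level a quadratic-
plateau curve y = a + bx + cx² (x ≤ x₀ = −b/2c, constant beyond) is fitted
by restarted least squares with continuity and zero slope at the join.
Degenerate cases are flagged: non-negative curvature falls back to the grid
argmax, flat data returns the left boundary, and a join outside the
searched range is clamped and flagged.

## Synthetic-data generator

Genotypes: ancestral allele frequencies uniform on `maf_range`,
subpopulation frequencies Beta-distributed around them with an Fst-like
divergence parameter (default 0.2; cluster-recovery tests use 0.3–0.4),
lines assigned randomly to subpopulations with each guaranteed nonempty,
inbred genotypes drawn as 2·Bernoulli with a small heterozygote rate
(default 2 %) and missing-at-random calls (default 10 %).

Phenotypes: marker effects are Gaussian on all markers (infinitesimal
model — the generating architecture is not known for real panels and this
is the assumption least favorable to any particular sparse method).  The
(environment, trait) covariance of genetic values is
w·Σ_E ⊗ Σt + (1−w)·J ⊗ Σt with w = `ge_variance` (default 1), so by
default the environment margin of the genetic values equals Σ_E exactly.
Default Σt, Σ_E, residual correlations, per-cell heritabilities, and trait
means are the values estimated for the wheat panel this package models
(e.g. rG(GY,HI) = 0.67, rG(SF,TGW) = −0.32, environment correlations
0.16–0.26, H² from 0.22 to 0.87).  Residual variances are solved per
trait × environment cell from the realized genetic variance so that
broad-sense heritability hits its target in expectation.  The field layout
is an augmented design: entries appear once per environment, checks once in
every block; days to heading is a line-level covariate with plot-level
jitter and configurable per-trait slopes (default 0, so heritability
targets are exact).

What the generator does *not* emulate: linkage disequilibrium beyond
subpopulation frequency structure, spatial field trends, outliers,
genotype-specific missingness, and selection history.  Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the stated generating model, not robustness to every
feature of real field data.

## Evaluation choices

- Fold construction is round-robin after shuffling (stratified: cluster by
  cluster with a single continuing pointer), which guarantees overall fold
  sizes and within-cluster counts each differ by at most one, for any seed.
- DAPC clustering retains the principal components explaining 90 % of
  marker variance (configurable), proposes groups by k-means (10 restarts),
  and converts them to posterior memberships with linear discriminants.
- Cross-validation masks validation lines in all environments at once by
  default (`mask_all_envs=False` gives the per-environment variant).
- Accuracy divides mean predictive correlation by √H²; the standard error
  is sd(r_p)/(√f·√H²).  Values may exceed 1 and are reported as computed;
  negative fold correlations enter means unchanged.
- Response to selection selects the top ⌈0.10·n⌉ lines by GEBV with ties
  broken by line ID, S is the selected-vs-population phenotype mean
  difference, R = H²·S, and the fold-level SE is sd(R)/√f.

## Problem sizes

The test suite and acceptance script run at desk scale by design: panels of
120–300 lines, 300–2,000 markers, and chains of 600–3,000 sweeps.  These
sizes were chosen once, from the parameter-recovery experiments, as the
smallest at which the stated tolerances hold with comfortable margin; the
samplers scale to full GBS panels (the 237 × 27,957 default of `SimConfig`)
without algorithmic changes because every update is eigenbasis-diagonal or
a batched L×L solve.

## Known limitations

- Mean imputation ignores LD; imputation accuracy is the masked-truth RMSE
  bound only.
- BLUE standard errors omit BLUP uncertainty in the environment and G×E
  predictions.
- Σ_E (environment-correlation) posteriors are weakly identified at small
  n (see above).
- The networks run on CPU only and implement exactly the three-layer dense
  architecture; no convolutional or attention variants.
- Heritability from augmented designs leans entirely on the repeated
  checks; with very few checks per environment the REML estimate is noisy
  and can hit the zero boundary.
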