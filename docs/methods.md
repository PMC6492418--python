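# Methods

## Model and estimands

We work with the sparse linear phenotype model y = W u* + e on a
column-standardized genotype matrix W (m individuals × n SNPs), residuals
e ~ N(0, σe² I). The estimand is SNP heritability, expressed either as
h² = τ²/(τ²+σe²) with τ² = u*ᵀΣu* (effects fixed, genotype rows random
with covariance Σ) or as h² = sσu²/(sσu²+σe²) (effects random on a support
of size s). For i.i.d. effect draws the two definitions coincide because
E[u*ᵀΣu*] = σu² tr(Σ_M0) = sσu² when standardized SNPs give Σ unit
diagonal; the test suite checks this identity by Monte Carlo rather than
assuming it.

Both heritability definitions live in (0,1); any estimate whose raw ratio
falls outside is reported as exactly 0.0001 or 0.9999 with a `clipped`
flag, so boundary pile-ups remain visible in downstream summaries.

## Two-stage procedure

1. **Split.** The sample is partitioned uniformly at random into halves of
   size ⌊m/2⌋ and ⌈m/2⌉. Selection sees only half 1; variance estimation
   sees only half 2. The diagnostic hook `estimation_half="training"`
   deliberately breaks this independence to demonstrate the resulting
   overestimation; it is never used for reporting.
2. **Selection.** Elastic net with objective
   (1/2m₁)‖y⁽¹⁾−W⁽¹⁾u‖² + αλ‖u‖₁ + ((1−α)/2)λ‖u‖₂². The denominator uses
   the fitted row count m₁ (a pure rescaling of λ relative to writing the
   full-sample m there, documented so λ values are comparable across
   tools). For each α in a configurable grid, a geometric λ path of
   `n_lambda` points from λ_max = max_j |W_jᵀy|/(m₁α) down to
   `lambda_min_ratio`·λ_max is cross-validated with 10 folds (contiguous
   blocks of one seeded shuffle, shared across the whole grid). Per α the
   one-SE rule picks the **largest** λ within one standard error of the
   minimum mean CV MSE (the conventional, sparsest-model direction;
   `one_se_direction="dense"` gives the opposite reading, i.e. the
   smallest such λ). The final α is the one whose path minimum is
   smallest, ties broken toward the larger α. The model is refit at the
   chosen pair on all of half 1; its support M̂ goes to stage 2.
3. **Variance estimation** on (y⁽²⁾, W⁽²⁾_M̂), y⁽²⁾ centered (and any
   covariates projected out beforehand; the projection reduces the
   degrees-of-freedom bookkeeping by q).

### Method-of-moments branch

With S = (1/m₂)WᵀW over the selected columns, d₁ = tr(S)/n̂ and
d₂ = tr(S²)/n̂ − (tr S)²/(n̂m₂) (computed on whichever of WᵀW / WWᵀ is
smaller, so wide panels never materialize an n̂×n̂ matrix), and
c = d₁/(m₂(m₂+1)d₂):

    τ̂²  = −n̂ d₁ c ‖y‖² + c ‖Wᵀy‖²
    σ̂e² = (1 + n̂d₁²/((m₂+1)d₂)) ‖y‖²/m₂ − c ‖Wᵀy‖²

These are the default (`formula="reference"`) forms. They satisfy
τ̂² + σ̂e² = ‖y‖²/m₂ identically — the estimator decomposes the total
phenotypic variance — and are Monte-Carlo unbiased at Σ = I in both the
classical (m₂ > n̂) and high-dimensional (n̂ > m₂) regimes. A `literal`
variant with a d₂² factor in the τ̂² lead term and a 1/n̂ total-variance
factor in σ̂e² is also shipped; it fails both the decomposition identity
and the unbiasedness check (its σ̂e² scales like m₂/n̂), which is why
`reference` is the default. The standard error of the clipped ratio is a
nonparametric bootstrap over individuals (default 200 resamples),
recomputed entirely from the m₂×m₂ Gram matrix so its cost is independent
of n̂; a single-resample bootstrap degenerates to SE 0 by convention.

### GREML branch

y⁽²⁾ ~ N(Xβ, σg²K + σe²I) with K = WWᵀ/n̂ and X the intercept. Because
there is exactly one GRM plus a residual, REML needs no iterative solver:
K is eigendecomposed once, y rotated, and the restricted likelihood
profiled over h = σg²/(σg²+σe²) on [1e-6, 1−1e-6] — a 64-point dense grid
followed by bounded Brent refinement (xatol 1e-10), with a guard that the
refined optimum never falls below the best grid point. This matches a
brute-force 1e-3-step grid maximization to |Δh| ≤ 2e-3 by construction and
is deterministic. A GRM whose eigenvalue spread is below 1e-8 (numerically
∝ I) is rejected as non-identifiable, since only σg²+σe² would enter the
likelihood. The delta-method SE uses the average-information matrix at the
optimum (observed information via central differences behind
`info="observed"`); the gradient of the ratio is
g = (σe², −σg²)/(σg²+σe²)².

When covariates were projected out upstream, the REML degrees of freedom
are reduced by their count but the log|XᵀV⁻¹X| term is evaluated for the
intercept only (the projected columns no longer exist). This is exact for
the no-covariate case, which is every internal use; with q projected
covariates it perturbs the criterion by an O(q) additive term that does
not depend on h to first order.

## Synthetic cohorts

The generator emulates the statistical structure the estimators assume:

* **Genotypes.** Per SNP a true allele frequency p_j ~ Uniform(0.05, 0.5)
  (the MAF law is a modeling choice; bounds configurable). Two latent
  Gaussian haplotype vectors per individual follow an AR(1) process with
  correlation `ld_rho` (default 0.5) inside blocks of `ld_block_size`
  (default 100) consecutive SNPs; thresholding each at Φ⁻¹(p_j) and
  summing yields Binomial(2, p_j) marginals (Hardy–Weinberg) with
  correlated neighbors (an LD surrogate). Defaults were fixed once as
  desk-scale stand-ins for typical common-variant panels.
* **Effects.** s support indices drawn uniformly without replacement,
  weights i.i.d. N(0, 1/s), so the expected genetic variance is 1
  regardless of s and h² ≈ 1/(1+σe²).
* **Noise.** e ~ N(0, σe² I); σe² ∈ {4, 1, 0.25} are the canonical levels
  giving h² ≈ 0.2, 0.5, 0.8.
* **Truth.** The realized heritability of a cohort is
  h̃* = (‖Wu*‖²/m)/(‖Wu*‖²/m + σe²); at m=1000, n=10000 its
  replicate-to-replicate SD is below 0.02, so it serves as the per-cohort
  ground truth.

One master seed spawns independent substreams for genotypes, effects and
noise (and one per replicate in the harness), so every replicate is
individually reproducible.

What the generator does **not** emulate: population structure and
relatedness, selection pressure, realistic MAF spectra, long-range LD, or
non-Gaussian residuals. Passing tests therefore demonstrate correctness of
the estimators under their stated assumptions, not robustness to
confounding in real cohorts.

## Experiment harness and problem sizes

The harness replays the canonical scenario grids as named presets
(noise-level, sample-size, SNP-count and sparsity panels, plus the
two-stage-versus-baselines panels at s ∈ {10, 100, 1000, 10000}). The
desk-scale defaults are 30 replicates with n capped at 10000
(`fig3*_scaled`); the full-size n=100000 presets exist for cluster runs.
For the two-stage presets the selector uses α ∈ {0.5, 1.0}, a 40-point λ
path to ratio 0.05, and single-precision fold fits — the CV fold fits only
shape the MSE curves, while the final refit is always double precision and
KKT-checked at 1e-6. Baselines (`full`, `oracle`) use the same
half-sample split as the two-stage runs for a like-for-like variance
comparison (`baseline_full_sample=True` switches to whole-sample
baselines).

## Numerical choices and edge cases

* Standardization uses sample allele frequencies over non-missing calls on
  the full QC'd panel **before** splitting, so both halves share one
  design; missing genotypes are 0 after standardization (mean imputation).
  Monomorphic SNPs are an error naming the SNP.
* QC: call rate ≥ 0.99, MAF ≥ 0.01, Hardy–Weinberg exact-test p ≥ 1e-6
  (full enumeration over heterozygote counts, non-mid p, the PLINK
  convention). Filtering is idempotent.
* Elastic-net coordinate descent is delegated to scikit-learn, whose
  penalized objective is identical under alpha↦λ, l1_ratio↦α; every
  returned fit is verified against the subgradient conditions at 1e-6 and
  a violation raises with the residual.
* λ = 0 falls back to the minimum-norm least-squares solution.
* A CV fold whose training phenotype has zero variance is skipped with a
  warning.
* d₂ ≤ 0 (no dispersion in the design covariance) raises a degenerate-
  design error; an all-zero phenotype yields τ̂² = σ̂e² = 0 with an
  undefined (NaN) ratio rather than a fabricated heritability.
* Empty selection (n̂ = 0) is reported as h² = 0.0001 on both branches
  with an `empty_selection` flag.
* GRM files use the GCTA binary dialect (float32 lower triangle), so
  round trips are bit-exact at float32 precision.

## Known limitations

* The moment estimator's finite-sample variance grows roughly with
  (1 + n̂/m₂); with very small halves (m₂ ≲ 150) and dense models it
  frequently clips at the boundaries — visible in the sample-size panel.
* The bootstrap SE for the fixed branch and the delta-method SE for the
  GREML branch are calibrated within ~50% of the replicate SD in the
  tested regimes, not exact.
* Selection consistency is not guaranteed (and not claimed): with weak
  effects the selected set misses part of the support and the estimate
  targets the variance attributed to the selected SNPs — a lower bound.
* Single variance component only; no partitioned heritability, no
  case-control liability transformation, no X chromosome.
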