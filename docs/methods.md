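# Methods

## Model

For each microbial feature M (one OTU's CSS-normalized abundance) the
package fits a three-trait recursive structural equation model over
ADG_AL (average daily gain under ad libitum feeding, g/day), ADG_R
(gain under restricted feeding, g/day) and M:

    y = (Λ ⊗ Iₙ) y + X b + Z_l l + Z_c c + Z_u u + e

with trait order fixed as (ADG_AL, ADG_R, M) everywhere. Λ is strictly
structured: only λ_AL←M and λ_R←M (positions (1,3) and (2,3)) are free,
so M is causally upstream of both growth traits and the graph is
acyclic. Fixed effects are the batch-farm combination (5 levels) and
the weaning-weight class (2 levels), full-rank dummy coding with an
intercept. Litter effects l and cage effects c carry unstructured 3×3
covariances L₀ and C₀; genomic effects u carry G₀ ⊗ G with G the
genomic relationship matrix (VanRaden method 1, identity-blended);
residuals are independent across traits, R₀ = diag(σ²_e,AL, σ²_e,R,
σ²_e,M). The diagonal R₀ is what makes the acyclic structure
identifiable, and together with the triangular Λ it makes the
likelihood Jacobian unity, so the model can be fitted as a standard
multi-trait mixed model on the transformed responses
(I − Λ ⊗ Iₙ) y. Residual covariances are hard-fixed at zero, not
estimated.

Exactly one of the two ADG records exists per animal (the feeding
regime is assigned at weaning); M is observed for everyone. The missing
ADG record is handled by data augmentation rather than row dropping, so
every covariance full conditional uses balanced cross-products. This is
valid precisely because R₀ is diagonal: given the location effects, the
augmentation draws are independent across traits.

## Gibbs sampler

One scan updates, in order:

1. the structurally missing ADG records from their trait-specific
   residual conditionals (augmentation);
2. fixed effects b (flat prior) per trait from normal conditionals of
   the least-squares system;
3. litter and cage blocks: with a diagonal residual the 3q-dimensional
   conditional factors into q independent trivariate normals, solved as
   batched 3×3 linear algebra;
4. genomic effects in the eigenbasis of G: writing G = U D Uᵀ and
   rotating the residuals by Uᵀ leaves the data precision E⁻¹ ⊗ Iₙ
   invariant while the prior precision becomes G₀⁻¹ ⊗ D⁻¹, so the
   3n-dimensional conditional factors into n independent 3×3 problems.
   This eigendecomposition trick is what makes hundreds of replicate
   fits affordable on one CPU: a scan costs O(n²) for the two
   rotations, not O(n³) for a mixed-model solve;
5. λ_AL←M and λ_R←M from scalar normal conditionals (the observed M
   enters the two ADG rows as a regressor);
6. L₀, C₀ from inverse-Wishart conditionals on the effect
   cross-products; G₀ from an inverse-Wishart on the G⁻¹-weighted
   cross-products (computed in the eigenbasis as u~ᵀ D⁻¹ u~);
7. each R₀ diagonal from a scaled-inverse-chi-square conditional.

Chains are bit-reproducible for a fixed seed (a single
`numpy.random.Generator` drives every draw). Every saved draw is
checked positive definite at save time; a variance exceeding an
overflow guard aborts with advice to strengthen the priors.

### Priors

No standard prior specification exists for this model class (common
mixed-model software leaves its defaults undocumented), so the priors
here are the package's own weakly-informative choice:

* L₀, C₀, G₀ ~ inverse-Wishart(df = 5, scale = diag(0.5 × empirical
  phenotype variances)). df = 5 is the smallest integer giving a finite
  mean for a 3×3 matrix; the scale keeps draws on the phenotype scale
  and positive definite at n ≈ 400.
* each residual variance ~ scaled-inverse-chi-square(df = 4,
  scale = 0.5 × empirical variance).
* b and the structural coefficients: flat. A proper normal prior for λ
  is available (`ChainConfig.lambda_prior_var`); it exists because the
  joint-distribution calibration test needs a proper joint. Posterior
  sensitivity to these priors should be checked against any external
  results rather than assumed away.

### Chain lengths

Defaults are desk-scale: 20,000 iterations, 5,000 burn-in, thin 10
(1,500 saved draws) — enough for stable λ summaries on n ≈ 400 given
the sampler's mixing. Production-scale settings (e.g. 1,000,000 /
300,000 / 100) are plain configuration. The replicate suites in the
acceptance script use shorter chains chosen once as part of the study
conditions: 1,500/500/1 for the 200-replicate null-coverage suite
(n = 300) and 2,500/500/2 for the 20-replicate recovery suite
(n = 600). HPD intervals from ~1,000 draws carry a little extra Monte
Carlo noise, which is symmetric and does not bias coverage in either
direction.

## Decomposition

All reduced-model ("starred") quantities follow from
Θ₀* = (I₃−Λ)⁻¹ Θ₀ (I₃−Λ)⁻ᵀ. The scalar identities used for reporting —
total = direct + indirect with indirect = 2λ_t σ_{u,M,t} + λ_t² σ²_{u,M}
for variances, λ_t σ²_{u,M} for trait–M covariances, and
λ_AL σ_{u,M,R} + λ_R σ_{u,M,AL} + λ_AL λ_R σ²_{u,M} for the mediated
ADG_AL–ADG_R covariance — are implemented separately from the matrix
transform and the two routes are cross-checked entrywise in the tests
and in `reduced_model_predictive_check`. Element (3,3) is invariant
(M has no upstream trait).

Because these identities are nonlinear in λ, every decomposed summary
is computed per draw and then posterior-averaged, never plugged in at
posterior means. Heritability uses the only denominator the model
admits — litter + cage + genomic + residual variance for the trait —
in both a "direct" (unstarred) and a "total" (starred) version, since
the two are genuinely different quantities under mediation.

Standardized effects divide the posterior-mean λ by a phenotypic SD.
The default is the observed SD of the trait; for ADG_AL the published
standardized effects back-calculate to an SD of ≈5.92 rather than the
tabulated descriptive 5.91 (they were evidently computed from unrounded
quantities), so the SD is an explicit argument and is recorded in the
result metadata. For ADG_R the tabulated SD of 5.27 reproduces every
published standardized effect to three decimals.

HPD intervals are the shortest contiguous window containing
⌈prob·n⌉ sorted draws, ties broken to the lowest starting index
(deterministic); significance is the HPD95% excluding zero; relevance
is |standardized effect| ≥ 0.2 SD, boundary included. No
multiple-testing adjustment is applied across OTUs — the per-OTU HPD
rule is the decision rule, by design.

## Synthetic data

The generator draws genotypes Binomial(2, p), p ~ U(0.05, 0.5) per SNP,
builds the GRM from them (or uses an identity GRM for very large
populations, where a dense n×n matrix would be pointless), draws
l, c, u, e from the model covariances (u through a Cholesky factor of
G so relatives share genetic values) and constructs traits in the
generative direction: M first, then each ADG with its λ·M term. Litters
are interleaved across cages so no cage holds more than two
litter-mates, matching the experimental design rule; the regime is
assigned 50/50 at random, independent of genotype and litter, and the
unobserved ADG is masked. The weaning-weight class is Bernoulli(0.5).

The default truth mirrors the study's scale: phenotypic SDs ≈ 5.9 and
5.3 g/day for the ADG traits and ≈ 1 CSS unit for M, ADG heritability
≈ 0.2, microbial-feature heritability ≈ 0.15, litter and cage shares
≈ 0.1–0.15, and structural coefficients of order 1 g/day per unit
(|λ/SD| in the "relevant" range).

What the generator does **not** emulate: count-level sequencing noise
(it emits the post-normalization continuous scale directly),
compositionality across OTUs, non-Gaussian abundance distributions,
genotype–environment correlation, and selection. Passing tests
therefore demonstrate that the estimator recovers the model it assumes
— not that real microbiome abundances satisfy those assumptions.

## Numerical choices and edge cases

* CSS normalization: per-sample scaling factor = sum of counts ≤ the
  sample's quantile-level positive count, fixed quantile 0.5. The
  original CSS publication's adaptive quantile search is deliberately
  not reproduced — the method is named, its tuning is not, and a fixed
  quantile is reproducible. The reference scale is the median scaling
  factor (count-like output scale); a fixed scale is available. An
  optional log2(x+1) transform is off by default and recorded in
  metadata, since whether the original units were logged is not
  documented; both scales are supported.
* Filtering boundaries: prevalence and relative-abundance values
  exactly at threshold are retained (the removal rule is strictly
  "less than"); "count sum less than 0.01%" is read relative to the
  grand total of all counts, the only unit-free reading.
* SNP QC order matches PLINK: individuals first, then SNP call rate,
  MAF and autosomal status computed on the retained individuals.
* GRM: VanRaden method 1 with observed allele frequencies; blend
  0.01·I by default so the eigendecomposition inside the sampler is
  safe; the blend weight is recorded in the output.
* ADG is the within-animal OLS slope of weekly body weight on age;
  fewer than two distinct ages is an error.
* Effective sample size: FFT autocovariance with Geyer
  initial-positive-sequence truncation; a constant chain warns and
  reports n.
* Degenerate model: `include_random_effects=False` pins l, c, u at
  zero, reducing the model to a fixed-effects regression with M as a
  covariate — the closed-form OLS cross-check used in the tests.

## Calibration evidence

Three independent checks back the sampler implementation:

1. a Geweke-style successive-conditional simulation on a tiny model
   (n = 30, 5 litters/cages) with all-proper priors (λ ~ N(0,1), fixed
   effects held at known values — a flat prior would make the joint
   improper and the check meaningless): the marginal chain of λ and the
   covariance components must match prior moments/quantiles; quantiles
   are compared rather than second moments because the df-5
   inverse-Wishart has infinite variance;
2. frequentist coverage of the λ HPD95% intervals across 200 null
   replicates (n = 300);
3. agreement of the degenerate model's posterior mean with OLS to
   within Monte Carlo error.

## Known limitations

* The per-OTU loop treats OTUs independently; no multivariate shrinkage
  across features and no compositional treatment.
* The sampler assumes the GRM fits in memory and is symmetric positive
  definite after blending.
* Heritability definitions assume the model's four variance components
  exhaust the phenotypic variance; any unmodelled source inflates the
  denominator estimate.
* The reported decomposition conditions on the fitted causal direction
  M → ADG; the model cannot itself adjudicate reverse causation.
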