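# Methods

This note documents the statistical models implemented in `skelstats`,
the choices made where the design was genuinely open, what the synthetic
cohort generator does and does not emulate, and the numerical conventions
that determine edge-case behavior.

## Data model

All statistics operate on a `subjects × skeleton-voxels` matrix
(`MetricStack`) tied to a `SkeletonSpace`: a 3D boolean mask with a fixed
C-order voxel↔column bijection, an affine for world coordinates, and
optional integer tract labels. Skeleton masks follow the TBSS
convention: voxels of the mean-FA skeleton with FA strictly greater than
0.2. DTI scalars derive from the sorted tensor eigenvalues
(λ₁ ≥ λ₂ ≥ λ₃): MD = mean, AD = λ₁, RD = (λ₂+λ₃)/2, and
FA = √(3/2)·‖λ − MD‖/‖λ‖ ∈ [0, 1], with FA of an all-zero tensor set to
0 by convention (with a warning), matching common tooling.

## Voxelwise GLM and permutation inference

Per-voxel OLS with a shared design matrix; contrast t-statistics use
residual df = n − p. Contrasts are one-sided (the analyses of interest
are directional: positive metric–performance associations, negative age
effects); both directions can be computed as separate maps. The engine
is closed-form and vectorized over voxels because permutation inference
refits every voxel for every permutation; unit tests pin it to
per-voxel `statsmodels` fits at 1e-8 relative tolerance.

TFCE integrates component extent^E × height^H over a threshold ladder
h = dh, 2dh, …, max(map), with dh = max(map)/steps. Defaults are H = 2,
E = 1, 26-connectivity and 100 steps — the usual choice for skeletonized
data, where the near-1D skeleton makes the volumetric E = 0.5 too weak;
`TFCEParams.volumetric()` provides the H = 2, E = 0.5 variant. Each
permuted map uses its own maximum for dh (standard practice); an explicit
`dh` override exists for comparing maps on a shared ladder. Negative
values are treated as zero for the enhanced direction, and an
all-nonpositive map enhances to zeros rather than erroring.

FWE control uses the permutation distribution of the maximum enhanced
statistic over the skeleton. Nuisance covariates are respected via
Freedman–Lane: the reduced (nuisance-only) model is fitted once, its
residuals are row-permuted, refitted under the full model, enhanced, and
the skeleton maximum recorded. The identity permutation is always
permutation 1, and the counting rule uses ≥, so p-values live in
[1/n_perm, 1] — with 5000 permutations the floor is exactly 0.0002.
Significance is strict (p < α). Fewer than 100 permutations is rejected
as an unusable null tail.

## Voxelwise Sobel mediation

Within an age-effect mask (FWE-significant negative age contrast on the
metric, controlling sex), the covariates are regressed out of age (x),
the behavioral score (y) and every voxel metric (m); by default the
residuals are z-scored so the paths are standardized and comparable
across voxels. Path a (and S_a) comes from OLS of m on x (df = n − 2);
path b (and S_b) from OLS of y on m and x jointly (df = n − 3) — b is
estimated controlling for x, the standard formulation when a direct
effect may exist. The Sobel statistic is

z = a·b / √(b²S_a² + a²S_b² + S_a²S_b²).

Two design choices deserve emphasis:

- **TFCE is applied to |z|.** The indirect effect's sign is a property of
  the construction (a negative age→FA slope times a positive FA→WM slope
  gives a·b < 0); enhancing only positive z would be blind to it. The
  signed z map is retained in the result.
- **The permutation null breaks only the b path.** The null is built by
  Freedman–Lane on the outcome model: y's residuals about its fit on x
  are permuted and b refitted, preserving both the age→metric
  association and the direct age→WM effect. The alternative — permuting
  the mediator — severs both paths at once and builds a "both nulls"
  reference; inside an age-effect mask every voxel carries a real a
  path, the observed z at a b-null voxel then behaves like a standard
  normal while the reference distribution is the much lighter
  product-normal, and the family-wise error explodes (in our replicates,
  essentially every null dataset produced significant voxels). Under the
  outcome permutation the composite null actually at stake (a ≠ 0,
  b = 0) is matched exactly, and the empirical FWE sits at the nominal
  level. The mirrored composite null (a = 0, b ≠ 0) cannot arise inside
  an age-effect mask by construction.

Constant-metric voxels are excluded from the mask with a logged count.
The peak voxel is the argmax of the enhanced map. The change-in-effect
summary fits y ~ age + sex and y ~ age + sex + metric(peak) and reports
both r², the age-coefficient t in each model, and two readings of the
"change": the literal relative r² change — which is non-negative for
nested models, since adding a regressor cannot lower r² — and the
attenuation of age's unique contribution (squared semipartial
correlation before vs after), which is the quantity that genuinely drops
when the mediator absorbs age-related variance. Both are reported side
by side because published summaries of this kind are ambiguous between
the two.

## Genotype and group statistics

Group contrasts are indicator-coded GLMs controlling age and sex, with
≥3 subjects required per level and listwise deletion per model. The
age × gene interaction is the product-term contrast of the indicator
with a binary age split (default boundary 60 years, configurable).
Hardy–Weinberg tests use allele frequency p = (2·hom₁ + het)/2n,
expected counts (np², 2npq, nq²) and the 1-df chi-square without
continuity correction; the reported frequency is for a caller-designated
allele. Demographic group tests are one-way ANOVA F for numeric
variables and a contingency chi-square for sex composition. Condition
comparisons enter both z-scored behavioral scores jointly and test the
(1, −1) slope-difference contrast — one defensible reading of "comparing
correlation coefficients" across conditions, chosen because z-scoring
makes the two slopes commensurable.

## The synthetic cohort generator

The generator emulates the data structure the analyses assume:

- **Ages** drawn from discrete narrow-age cohorts (25–80 in 5-year
  steps) with weights skewed toward older participants, mirroring the
  study-scale group sizes; a different cohort list is one parameter away.
- **Genotypes** at three loci, multinomial with Hardy–Weinberg
  probabilities at allele frequencies (0.192, 0.562, 0.471) — the
  study's observed values.
- **A latent white-matter factor** f = a·z_age + √(1−a²)·e_f with
  standardized planted path a (default −0.4).
- **Working-memory accuracies** for manipulation/maintenance/control:
  latent g_c = direct_c·z_age + b_c·f + λ·u + residual, with
  load-graded direct age slopes (defaults −0.33, −0.22, −0.12), the b
  path (default 0.3) entering the manipulation condition, and a shared
  ability factor u (loading 0.8) inducing the high inter-condition
  correlations seen in such batteries. Scores map to the accuracy scale
  as clip(18 + 2.5·(g_c − direct_c·z_min), 0, 18), so the youngest
  cohort sits at the 18-item ceiling (as real control-condition data
  do) and scores are continuous rather than integer — preserving the
  correlational structure is the point, not the marginal distribution.
  Gaussian residuals are an assumption; the residual SD is derived to
  give unit latent variance unless set explicitly (setting it to 0 with
  zero slopes collapses all scores to the ceiling).
- **The FA stack**: a designated block of "mediating" voxels carries
  m = a·z_age + √(1−a²)·(√(1−τ²)·e_f + τ·ε), sharing e_f with the
  cohort's factor so the voxel-level paths are a exactly and
  b·√(1−τ²); a spatially separate block carries the age effect only;
  the rest is pure noise. τ = 0.3 keeps effect voxels distinct while
  attenuating b by under 5%. Latents map to FA as 0.5 + 0.08·m, clipped
  to (0.01, 0.99). Effect-voxel index sets depend only on the space and
  spec — never on the seed — and occupy contiguous C-order blocks
  separated by a guard gap, so TFCE sees clustered signal and the two
  blocks are not 26-connected.
- **Processing speed**: sum of three z-scored subscores, each with a
  −0.55 standardized age slope.
- A single seed drives everything through deterministic per-stage
  substreams; sex is Bernoulli (52.7% female) and induces no effect
  unless configured.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatial autocorrelation of measurement noise
along the skeleton (noise is i.i.d. across voxels), registration and
skeleton-projection error, crossing-fiber geometry, realistic tract
shapes (labels are synthetic slabs), non-Gaussian score distributions and
integer accuracies, site/scanner effects, and any genotype→FA or
genotype→behavior effect (none is planted by default). Calibration
results therefore speak to the inference machinery under the assumed
model, not to robustness against those real-world violations.

## Validation experiments and problem sizes

`skelstats.validation` packages the self-checks: the permutation floor
demonstration (n = 60, 500 voxels, 5000 permutations, planted
overwhelming effect), the TFCE lone-voxel closed form (height 3 → 3³/3,
discrete sum within 2% at 200 steps), the null FWE calibration (200
independent noise datasets, n = 60, 500 voxels, 300 permutations, TFCE
at 32 steps — the step count does not enter the FWE contract since
observed and null maps share the enhancement), and planted-mediation
recovery (n = 200, 2000 voxels, 500 permutations, a = −0.4, b = 0.3).
In the recovery experiment the detection power and false-positive rate
come from one cohort's full inference run; the recovered path
coefficients are averaged over the planted voxels of 48 replicate
cohorts, because a single cohort's subject-level sampling error
(sd ≈ 0.06 for b at n = 200) is shared by every voxel and cannot be
averaged away within one dataset — the replicate mean is the quantity
whose calibration is claimed.

## Known limitations

- No variance smoothing and no cluster-extent/mass alternatives to TFCE.
- No bootstrap mediation intervals, multiple mediators, or longitudinal
  causal mediation; like any cross-sectional mediation, significant
  indirect effects are associations, not causal claims.
- The permutation engine labels components per threshold step per
  permutation; it is comfortable at desk scale (~10³–10⁴ skeleton
  voxels) but is not engineered for full-resolution skeletons at 5000
  permutations in interactive time.
- Real-data mode expects already-skeletonized 4D stacks; registration,
  projection and tensor fitting are out of scope.
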