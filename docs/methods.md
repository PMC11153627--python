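# Methods notes

This note records the modelling and numerical choices behind `molnorm`,
what the synthetic generator does and does not emulate, and the known
limitations.  It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dual-regression estimator

The two-stage estimator is ordinary least squares throughout; both stages
are verified against pseudo-inverse oracles to 1e-8 in the test suite.
Conditioning choices, where the literature leaves room:

* **Template conditioning.** Each molecular template is min-max rescaled
  to [0, 1] within the grey-matter mask (zero outside).  Pearson
  correlations between templates — and hence the VIF collinearity
  diagnostics — are invariant to this affine rescaling; it only pins the
  scale of the stage-1 design.  The rescaling function is separate and
  swappable.
* **Stage 1** demeans each volume across in-mask voxels and includes an
  intercept, so global signal offsets (including the additive site offset
  of the generator) cannot leak into the system time series.
* **Stage 2** z-scores each system time series and includes an intercept,
  making betas comparable across systems with different stage-1
  amplitudes.  Consequently betas scale linearly with BOLD amplitude
  (scale covariance is property-tested).
* **No confound regressors** (motion, drift): preprocessing is declared
  upstream and out of scope.
* **Missing ROIs** (no in-mask voxels) parcellate to NaN with a warning,
  never silently dropped, so the subject × ROI × system array has a stable
  shape.
* VIF ≥ 5 (the usual rule-of-thumb concern level) warns but does not
  error; estimation remains defined as long as the design has full rank.

## Hierarchical Bayesian normative model

Per (ROI, system): `y = b0 + b_age·age + b_sex·sex + u_site + ε`, with
site offsets `u_s ~ N(0, τ²)` drawn from a shared prior and site-specific
noise `ε ~ N(0, σ²_s)` tied across sites through a shared hyperprior.
Noise is homoskedastic in covariates within site (no age-dependent
variance).

Two engines implement the same model:

* **Gibbs sampler** (`mode="gibbs"`): all full conditionals are conjugate.
  Fixed effects carry Normal(0, (10·sd(y))²) priors (scaled per column);
  τ² and σ²_s carry Inverse-Gamma priors, with the σ²_s rate itself
  Gamma-distributed and Gibbs-updated, which is what ties the site noises
  together.  Conjugate variance priors were chosen over half-normal ones
  precisely so that every update is exact closed form and the sampler
  needs no autodiff machinery or tuning.  Defaults: 2 chains × (1000
  warmup + 1000 draws), convergence requires max split-R̂ < 1.05 over the
  coefficients; non-converged cells are flagged and excluded by retention,
  never raised.
* **Closed-form mode** (`mode="eb"`, default): feasible GLS with per-site
  intercepts and shared age/sex slopes; per-site residual variances are
  lightly shrunk toward the pooled value (weight 5 pseudo-observations)
  and re-used as weights for one refit.  The coefficient sampling
  covariance stands in for the posterior covariance.  This mode is
  deterministic and orders of magnitude faster, which is what makes
  fitting hundreds of (ROI, system) cells inside a test run practical.
  On the synthetic designs used here its predictions and predictive
  variances agree closely with the sampler's; the sampler remains the
  reference implementation of the hierarchical model.

**Deviation scores** use the *full* predictive sd — coefficient
uncertainty `x'Σx` plus the subject's site noise variance — rather than
noise sd alone, reading "prediction uncertainty" as predictive
uncertainty.  With noise-only sd the held-out variance target would be
approached from above as n grows; with the full sd held-out healthy
z-scores are calibrated (mean ≈ 0, variance ≈ 1) at the sample sizes
tested.  Patients are scored with the same trained models as held-out
controls.

**Split bookkeeping.** The 70/30 healthy train/test split takes the total
test count as the ceiling of fraction × N and apportions it across sites
by largest remainder, then randomises membership within site by seed.
This reproduces the canonical 496/111 → 150/33 held-out counts.

**Retention.** ROIs enter downstream analyses only when their held-out
explained variance is strictly positive *and* the sampler converged.
Retention is decided on healthy data alone, so masks are identical across
diagnostic groups by construction.

## Symptom reduction

Measures are z-scored (population sd) across all patients pooled
transdiagnostically, then decomposed by eigendecomposition of the
correlation matrix — equivalent to covariance PCA on standardised data.
No rotation.  Components with eigenvalue > 1 are retained.  Signs are
fixed deterministically (largest-magnitude loading positive) because they
are mathematically arbitrary but tests need bit-identical reruns.
Standardisation uses patients only: healthy controls carry no symptom data
in this design.  More measures than subjects is a warning (rank
deficiency), not an error.

## Similarity analyses

Pearson correlation is the similarity measure throughout (Spearman is
exposed as an option).  Deviation similarity for a system uses only that
system's retained ROIs, since unretained cells carry no valid z.  Group
summaries always exclude the subject from their own average.

The Friedman test uses within-subject average ranks; Conover post-hocs use
the rank-sum t form on (n−1)(k−1) degrees of freedom with Bonferroni over
the k(k−1)/2 pairs.  Below five subjects the χ² approximation is replaced
by a within-subject label-permutation p-value, with a warning.

Two-sample KS tests on within-group similarity distributions use exact
p-values when either sample has fewer than 25 values, asymptotic
otherwise.  The Bonferroni family for these tests is systems × clinical
groups (6 × 3 = 18 in the full design); for the transdiagnostic
correlates it is systems × (1 mean-deviation + retained components)
(6 × 5 = 30 with four retained components).

## Permutation inference

Free permutation of group labels (or component scores) is valid here
because the designs are single-factor exchangeable; no
exchangeability-block structure is supported.  p-values use the add-one
convention `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, which is exact and
never returns zero.  Default `n_perm = 2000`.  FDR is Benjamini–Hochberg
within each system (and within each system × component family for the
symptom mapping), matching per-network reporting; two-sided inference for
t contrasts and regressions.  The deviation–symptom statistic is the
simple-regression/Pearson t (for one regressor they are monotonically
equivalent).  All statistics are bit-reproducible given (data, seed,
n_perm).  The identical code path runs on raw FC values via the
``values=`` argument, for the conventional-analysis contrast.

ROC AUC is computed by the rank (Mann–Whitney) formulation on the logistic
model's predicted score, so it is invariant to monotone rescaling of the
predictor and reflects discrimination regardless of the direction of the
group difference.  Perfect separation keeps AUC defined (1.0) and flags
the coefficient as non-converged.

## Synthetic generator

The generator is first-class, tested code; its defaults are the study
conditions every calibration and recovery test runs under.

* **Templates**: smooth Gaussian random fields, empirically
  orthonormalised over in-mask voxels and remixed through the Cholesky
  factor of an equicorrelation matrix, so realised pairwise correlations
  hit the target exactly (default 0.3, the moderate collinearity regime;
  any admissible equicorrelation keeps VIF < 5).  Min-max rescaling makes
  them nonnegative without changing correlations.
* **BOLD**: `BOLD(v,t) = Σ_k s_k(t)·m_k(v) + b_site + ε(v,t)` — the exact
  generative inverse of the dual regression, with unit-variance AR(1)
  latents (coefficient 0.5) and Gaussian noise at the configured SNR
  (default 5).  Demographic structure enters through per-system amplitude
  gains (age, sex, site), so ROI betas inherit age/sex/site effects when
  the full BOLD route is used.
* **ROI-level route**: for normative and inference testing the subject ×
  ROI × system table is also drawn directly from the planted linear model
  (intercepts, age slopes ~N(0, 0.01), sex offsets ~N(0, 0.3), site
  offsets ~N(0, 0.5), log-normal site noise around sd 0.5), which makes
  ground-truth recovery exact to state rather than filtered through the
  estimator.
* **Deviations**: each clinical group shifts its own block of 10 ROIs in
  one system by −1 healthy residual sd (both knobs configurable).  Shifts
  are expressed in residual-sd units estimated from the healthy subjects,
  so "−1" is exactly one normative-model noise unit.  Effect sizes of real
  clinical cohorts in FC units are not established; this default is a
  free parameter chosen as a moderate, recoverable effect, not a
  calibration to any dataset.
* **Symptoms**: 28 measures = 4 standard-normal factors × loadings +
  noise, with a dominant loading block per factor; factor 2 is coupled
  (Pearson 0.6 by construction) to each patient's planted deviation
  burden, so the deviation–symptom mapping has a recoverable
  transdiagnostic signal.  Patients only, mirroring designs where a single
  clinical site is deeply phenotyped.
* **Determinism**: one master seed spawns fixed, purpose-keyed substreams
  (templates, cohort, truth, per-subject noise, symptoms), so identical
  configs give bit-identical outputs and components can be regenerated
  independently.

What the generator does **not** emulate: realistic fMRI artefacts (motion,
drift, physiological noise), preprocessing, spatially heterogeneous
haemodynamics, non-Gaussian noise, site-by-covariate interactions, and
real PET template geometry.  Passing tests therefore demonstrate that the
estimators recover the structure they assume, at realistic sample sizes
and noise levels — not that the pipeline is robust to artefact-laden real
data.

## Problem sizes

Test and acceptance runs use a 12³ voxel grid (sphere-masked), 2–6
systems, 10–60 ROIs, cohorts of 80–672 subjects, 500-replicate null
batteries with 500–2000 permutations, and the closed-form normative mode
for grid fits with the Gibbs sampler on targeted cells.  These sizes were
chosen so the whole battery runs comfortably on a laptop-class single
core while leaving the statistical tolerances meaningful.

## Known limitations

* No warped or non-Gaussian likelihoods, no Gaussian-process normative
  variants, no transfer/adaptation to sites unseen in training (scoring an
  unseen site is a hard error by design).
* Single-factor permutation only; no repeated-measures or family
  exchangeability blocks.
* The closed-form normative mode understates posterior uncertainty
  slightly relative to the sampler when site counts are very small.
* Volumes must share shape and affine exactly; there is no resampling.
* No voxelwise group inference, spatial smoothing or surface rendering.
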