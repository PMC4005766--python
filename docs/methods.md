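# Methods

## The model

Energy expenditure is measured as VO2 in ml O2 per kg body weight per
minute, and heart rate (HR) in beats per minute, once per subject at each of
five exertion levels: rest, slow walking, customary walking, peak sustained
walking, and maximal exertion. For subject *i* at measurement *j* the model
is a linear mixed model with a random intercept and a random slope on heart
rate:

    y_ij = x_ij' β + b_0i + b_1i · HR_ij + W_ij
    (b_0i, b_1i) ~ N(0, G),  G unconstrained 2×2
    W_ij ~ N(0, σ²), iid

Two fixed-effect designs are supported:

* **m1 (stratified)** — separate intercepts and HR slopes for four sex/age
  groups (men < 65, men ≥ 65, women < 65, women ≥ 65), coded as contrasts
  against men < 65: `(1, G2, G3, G4, HR, HR·G2, HR·G3, HR·G4)`. The age-65
  boundary assigns age 65 itself to the older group.
* **m2 (continuous age)** — `(1, HR, male, age, age·HR)`; no age centering,
  so coefficients are on the raw scale.

The random-effect design is `(1, HR)` in both forms. G is reported as
`sd_b0`, `sd_b1` and their correlation `corr_b`; the residual as `sd_resid`.
Heart rate is treated as a fixed covariate (no measurement-error model), and
height is accepted in input tables but not used: only the two final designs
above are implemented.

## Estimation

The marginal likelihood factorizes over subjects with per-subject covariance
`V_i = Z_i G Z_i' + σ² I`. We optimize over the three-parameter log-Cholesky
factor of `D = G/σ²` — positive semidefiniteness is guaranteed by
construction and the surface stays smooth near `|corr| → 1`, which matters
because the fitted correlation (~−0.87) sits near the boundary. For fixed D,
β is profiled out by generalized least squares and σ² in closed form
(`RSS/N` for ML, `RSS/(N−p)` for REML, with the REML objective carrying the
`log|X'V⁻¹X|` correction). The GLS solve uses QR on the whitened, stacked
design rather than the normal equations: the `age·HR` column reaches ~2·10⁴
and the normal equations lose ~6 digits there.

ML is the default and is what the replication experiments use; REML is
available. Both objectives agree with `lme4` and statsmodels `MixedLM` at
matched parameters to <1e-7 (the test suite asserts the statsmodels ML check
at 1e-4).

Optimization runs L-BFGS-B on numerical gradients followed by a Nelder–Mead
polish from three dispersed, data-driven starts (per-subject OLS moments and
two spread-out perturbations of them). Non-convergence is reported on the
result object, never raised. Standard errors: fixed effects from the GLS
covariance `σ²(X'V⁻¹X)⁻¹` with Wald z-tests (no degrees-of-freedom
correction); variance components by the delta method from the numerically
differentiated observed information in the unconstrained parameterization,
mapped to the sd/correlation scale. SEs are reported as NaN when a component
sits essentially on the boundary (sd ≈ 0 or |corr| ≈ 1), where the
information matrix is meaningless.

## Calibration (BLUP)

Given a fitted model and k calibration measurements of one subject, the
conditional distribution of (b_0i, b_1i) is the usual empirical-Bayes/BLUP
computation at plug-in (β̂, Ĝ, σ̂²):

    mean = G Z'(Z G Z' + σ²I)⁻¹ (y − Xβ̂)
    cov  = G − G Z'(Z G Z' + σ²I)⁻¹ Z G

with Z the k×2 matrix of rows (1, HR). k = 0 returns the prior — this is the
"no calibration, subject effects set to zero" case. Residuals always use the
training fit's fixed effects; nothing is refit per subject, mirroring the
use of a published equation plus personal calibration points. Predictions
are `x'β̂ + b̂_0 + b̂_1·HR` with variance `z'Cz + σ²` (C the posterior
covariance, or the prior G without calibration). The kcal conversion is
5 kcal per litre of O2: `kcal/min = VO2 · weight/1000 · 5`; a per-minute
bias extrapolates to kcal/day by ×1440.

The four standard calibration scenarios are: none; rest only; rest plus peak
*sustained walking* (the 400 m fast walk — not maximal exertion); and all
five levels.

## Cross-validation

Subjects are split 80/20 at the subject level (largest-remainder allocation
within the four sex/age strata when stratified; stratified is the default
for m1). The model is fit on training subjects only. For each validation
subject, the scenario's calibration rows give the posterior, and EE is
predicted at all five levels — including the calibration levels, which keeps
all scenarios on the same support (a `holdout_only` flag scores only
uncalibrated levels for sensitivity). Errors (observed − predicted) are
converted to kcal/min with each subject's own weight — the only choice that
keeps subject-level errors meaningful — then pooled across subjects and
levels into a single SD per scenario (n−1 denominator). Kernel density
estimates use a Gaussian kernel on 512 points spanning mean ± 4 SD with the
Silverman rule-of-thumb bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)`.

Replication has two layers: `run_scenarios` re-splits one cohort, and
`replicate_experiment` regenerates a fresh cohort per replicate (the
protocol used for the headline numbers, 20 replicates by default, each with
one split). Reported scenario SDs are replicate averages with per-replicate
values retained.

## The synthetic-data generator

The generator emulates the study design: n = 290 subjects, age from a
truncated normal on [32, 90] with mean 67.6 and SD 11.5, sex Bernoulli with
59.3% male, weight truncated normal 79.2 ± 14.4 kg on [45, 140] kg
(independent of sex and age, since only pooled moments are available). The
truncated-normal location is solved (Brent) so the *truncated* mean equals
the target — naive truncation would shift the age mean by −0.7 years.
Truncation shrinks the realised SDs slightly (age ~10.6 rather than 11.5);
means are matched exactly in expectation.

Heart rates at the five levels have means (61.2, 85.7, 97.8, 120.4, 148.6)
bpm and SDs (9.7, 12.9, 15.7, 19.8, 21.0). Within-subject dependence uses a
single latent fitness factor f_i ~ N(0,1):

    HR_ij = μ_j + s_j·(age − 67.6) + ρ·sd_j·f_i + ε_ij,
    ε_ij ~ N(0, sd_j²(1 − ρ²)),  ρ = 0.7 by default

so fit subjects run low at every level. This is a modelling stand-in — no
within-subject HR dependence structure is identified by the published
moments — and is configurable. Per-level age slopes default to
(0, 0, 0, −0.55, −1.05) bpm/year, reflecting the decline of peak and maximal
heart rate with age; they may be set to zero. The protocol's ordering
(HR non-decreasing across levels) is enforced by rejection sampling with 100
retries and a sort fallback. Because that enforcement conditions the joint
distribution, it would bias per-level means by 1–2 bpm; the generator
therefore calibrates the underlying level means with a short deterministic
fixed-point pilot simulation (fixed internal seed, independent of the cohort
seed) so post-enforcement sample means match the configured values to
~0.3 bpm. Set `calibrate_hr_means=False` for the uncorrected mechanism.

Energy expenditure is the mixed model itself: fixed effects default to the
m2 estimates (−23.046, 0.339, 2.241, 0.099, −0.0007), variance components to
sd_b0 = 3.966, sd_b1 = 0.062, corr = −0.874, sd_resid = 2.787. A stratified
variant (`GeneratorConfig.stratified()`) generates from the four-group
intercepts/slopes with that model's components (4.007, 0.063, −0.875,
2.785). Residual noise is homoscedastic Gaussian exactly as the model
assumes; no floor is applied by default, so a rare resting draw can be ≤ 0 —
model faithfulness is preferred over physiological realism, and an optional
`ee_floor` exists.

What passing tests on these cohorts show: the estimator, calibration, and
cross-validation machinery are correct for data that satisfy the model's
assumptions at the published parameter values. What they do not show:
robustness to real-data features the generator omits — nonlinearity near the
rest-to-activity transition, heteroscedastic measurement error across
analyzers, beta-blocker-type blunted responses, or missing levels.

## Reproducibility and numerics

All randomness flows from integer seeds through
`derive_seed(seed, stage)` — a `SeedSequence` spawned with a CRC32 hash of
the stage name — so any stage can be rerun in isolation and whole
experiments are byte-reproducible. Convergence is declared at relative
log-likelihood change below 1e-10 (simplex `fatol`). Degenerate inputs:
zero-variance generators produce exact interpolation and zero
cross-validation error; zero-variance error vectors yield a point-mass
density with a warning; subjects with constant HR are excluded from the
intra-person correlation summary with a warning. Replicates whose training
fit fails to converge are dropped from cross-validation summaries with a
logged warning.

The replication experiments use 20 cross-validation replicates (fresh
cohort, one split each) and 50 parameter-recovery fits at n = 290 — large
enough that replicate-mean Monte-Carlo error is well inside the comparison
tolerances, and small enough to run in a few minutes on one CPU.

## Known limitations

* Exactly one measurement per subject-level pair; no missing-data handling
  beyond validation errors.
* No small-sample df corrections (Satterthwaite/Kenward-Roger); z-tests
  only.
* General mixed-model features (crossed effects, >2 random terms,
  non-Gaussian outcomes) are out of scope.
* The latent-factor HR dependence and the per-level age slopes are
  plausible defaults, not estimates from data.
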