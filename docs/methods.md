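# Methods

## Model

For one segmentation method and one brain region, volumes `y` from a
healthy reference population are modeled with the LMS approach under the
Yeo–Johnson (YJ) transformation: at age `t`,

    z = ( ψ_{L(t)}(y / s0) − μ(t) − β_s·sex − β_h·(height − 170) ) / σ(t)

is assumed standard normal, where `ψ_λ` is the YJ transform

    ψ_λ(y) = ((y+1)^λ − 1)/λ            y ≥ 0, λ ≠ 0
           = log(y+1)                   y ≥ 0, λ = 0
           = −((1−y)^{2−λ} − 1)/(2−λ)   y < 0, λ ≠ 2
           = −log(1−y)                  y < 0, λ = 2,

`L(t)` the age-varying transform exponent, `μ(t)` and `σ(t)` the
transformed-scale location and scale, and `β_s`, `β_h` additive covariate
effects of sex (0 = female, 1 = male) and height centered at 170 cm. The
classical L/M/S curves are recoverable: the median at age `t` is
`s0·ψ⁻¹_{L(t)}(μ(t) + covariates)` and `S` is the implied coefficient of
variation. Patient volumes are converted to z-scores against the fitted
reference model; iso-z-score curves are obtained by applying the inverse
transform to `μ(t) + z·σ(t)`.

### Assumptions

- A single YJ exponent per age suffices to Gaussianize the volume
  distribution (no heavier-tailed families).
- Covariates act additively on the transformed-scale **location** only,
  not on L or S. This is the minimal covariate correction consistent with
  displaying curves for one reference stratum (males, 170 cm).
- Cross-sectional data; no longitudinal within-subject correlation.

## Fitting

- Each of `L`, `μ`, `log σ` is a natural cubic regression spline in
  standardized age with `δ` knots at age quantiles, so each curve has
  exactly `δ` degrees of freedom in the smoothing-spline convention
  (`δ = 2`, the default, is exactly linear in age; `δ = 3` adds one
  curvature term). The natural-spline basis is linear beyond the boundary
  knots, which keeps behaviour tame near the edges of the age range.
- All parameters (3δ spline coefficients + β_s + β_h) are estimated
  jointly by maximizing the exact log-likelihood, including the Jacobian
  term `(L(t)−1)·log(1+y/s0)` of the transformation, with L-BFGS-B
  (numerical gradients; relative tolerance 1e−12, at most 500 iterations).
- Initialization: `L ≡ 1` (identity transform), `μ` from least squares of
  the normalized volumes on the basis, `log σ` from the residual SD,
  betas at 0.
- `L(t)` is smoothly bounded to (−3, 3) via `3·tanh(·/3)` to prevent
  transform blow-up during optimization.
- Volumes are normalized by `s0`, the training-sample median, before the
  transform. This is purely a conditioning device (spline coefficients
  stay O(1) across regions whose medians span 1,700–12,500 mm³); since
  the skew-correcting leverage of a power transform depends on the
  *relative* spread of the data, the normalized family is equivalent to
  first order, and exactly equivalent at λ = 1. `s0` is stored in the
  model and undone in iso-curves.
- Fitting is refused below 50 observations or for constant volumes. An
  optimizer that stops on a line-search warning but has improved the
  objective to a finite optimum is accepted with `converged=False`
  recorded in the diagnostics; a diverged or non-improving run raises.
- Mean and SD of the training z-scores are recorded as diagnostics
  (expected ≈ 0 and ≈ 1), not enforced.
- Evaluation outside the fitted age range raises unless explicitly
  overridden; the analysis only ever evaluates in-range.

## Preprocessing

Order: (1) left+right hemisphere volumes summed (a record with only one
hemisphere is an incomplete segmentation and becomes a failure);
(2) caudate nucleus + accumbens merged into one region, since one method
family segments them jointly — pre-merged methods are auto-detected and
relabeled; (3) failed segmentations (missing or zero volume) removed;
(4) per region, reference volumes with population |z| > 5.0 excluded.

Outlier details: the mean and SD (n−1 denominator) are computed in a
single pass over all values, candidate outliers included — no trimming,
no iteration. The threshold 5.0 (rather than the customary 3.0) keeps as
much of the normal population as possible while rejecting implausible
volumes. Exclusion is region-scoped and uses the union rule: a subject
flagged by any method is removed from that region's analysis for all
methods, so each region ends with its own included-subject count. Patient
records are never auto-excluded by z-score; they are dropped only via an
explicit `exclude` flag in the input, standing in for visual inspection.

## Agreement statistics

`ICC(A,1)` is computed exactly from the two-way mean squares

    MSR = k·Σ_i (X̄_i − X̄)² / (n−1),   MSC = n·Σ_j (X̄_j − X̄)² / (k−1),
    MSE = Σ_ij (X_ij − X̄_i − X̄_j + X̄)² / ((n−1)(k−1)),

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)).

Pairwise matrices use complete-case assembly **per method pair**
(pairwise deletion), with the subject count recorded per cell; this
maximizes data use and matches the per-region accounting of the exclusion
step. Undefined statistics (constant input) are marked unavailable, never
reported as 0. Rating bands are closed on the left: [0.5, 0.7) is fair,
[0.7, 0.9) good, ≥ 0.9 excellent — the boundary value goes to the upper
band. ICC confidence intervals are out of scope (point values only).

The AUC uses midranks, so ties receive the Mann–Whitney half credit. The
95% CI is a percentile interval from stratified bootstrap resampling
(within-group, preserving group sizes; default 1,000 replicates). The
closed age window [71, 91] restricts reference subjects only.

## Synthetic cohort generator

The generator is latent-variable by construction: each subject carries one
true volume per region,

    v = ψ⁻¹_λ( ψ_λ(m(age, sex, height)) + σ_t·z ),   z ~ N(0,1),

with `m` linear in age plus additive sex/height effects and `σ_t` chosen
by the delta method so the coefficient of variation of `v` matches the
configured value (the median maps exactly: z = 0 gives `v = m`). Patients'
latent volumes are multiplied by a per-region atrophy factor before
observation. Each method observes `scale·v + offset + N(0, noise_sd)`,
with failures (missing volume) and gross outliers (+8 population SDs)
injected at configured rates. Hemispheres are emitted as a fixed 48/52
split of the total so merging is deterministic; one method reports
caudate+accumbens pre-merged (the others emit a 14:1 split) so the region
merge is exercised end to end. `true_z` inverts the generative model and
is the oracle for parameter-recovery tests.

Defaults are the study conditions: 988 reference subjects uniform over
ages 45–95, 42 patients uniform over 71–91, six subcortical regions with
medians/CVs in the published range (thalamus 12,400 mm³ at CV 0.13 down
to globus pallidus 2,300 mm³), five methods with distinct offsets
(−150…+400 mm³), scalings (0.92…1.12) and noise (80–150 mm³), failure
rates up to 0.9%, and atrophy of 0.75/0.78 in hippocampus/amygdala versus
0.95–0.96 elsewhere. Because offsets are absolute, small regions lose
absolute agreement faster than large ones — the same pattern the real
methods show. Heights are drawn N(163, 7) / N(177, 7) cm by sex.

What the generator does **not** emulate: atlas-specific boundary
disagreements that vary by subject morphology (its distortions are global
affine plus noise), scanner/protocol effects, age-varying method bias, and
spatial correlation between regions. Passing tests therefore demonstrate
the statistical machinery is correct under the declared model, not that
any particular pair of real methods is interchangeable.

## Numerical choices

- YJ transform and inverse use the `expm1`/`log1p` formulation, accurate
  and continuous across the λ = 0 and λ = 2 branch points; the inverse
  raises a domain error outside the transform's image.
- Sample SDs use the n−1 denominator throughout.
- Outlier removal is single-pass (no iteration to stability).
- AUC ties: 0.5 credit (measure-zero for continuous z but fixed for
  reproducibility).
- All randomness flows from explicit seeds; per-cell bootstrap seeds are
  derived from the master seed and the (method, region) label via a CRC,
  so adding a region never perturbs another region's interval.
- Row order of the training data does not affect fitted curves beyond
  floating-point round-off of reordered sums.

## Problem sizes

Parameter-recovery and calibration checks run 20 replicates of n = 2,000
single-region cohorts; ICC sensitivity checks use n = 10,000 draws;
the end-to-end determinism check runs the full pipeline twice on a reduced
cohort (3 methods, 6 regions, 400/30 subjects). These sizes give
Monte-Carlo error comfortably inside every asserted tolerance while
keeping the whole suite under a minute.

## Known limitations

- δ = 2 yields age-linear norms; real lifespan trajectories curve, and a
  user wanting curvature must raise δ (the basis supports it) at the cost
  of more data per fit.
- The likelihood is optimized with numerical gradients; for very large
  δ the optimization may need more iterations than the default budget.
- λ is weakly identified when the volume distribution is nearly symmetric
  (any λ then fits equally well); this does not affect median curves or
  z-scores, only the interpretability of L itself.
- Scenario-2 cross-method z-scoring (`cross_method_z`) is a demonstration
  of the failure mode, not a recommended analysis path.
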