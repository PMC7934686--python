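# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `dtifitlab`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tensor estimation

All fits invert the single-tensor Stejskal–Tanner model
`S_i = S0 exp(−b_i g_iᵀ D g_i)` per voxel.  The log-linearized design matrix
has one row per volume, `[1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz,
−2b gy gz]`, acting on the parameter vector `(ln S0, Dxx, Dyy, Dzz, Dxy,
Dxz, Dyz)`; its rank is checked at construction so degenerate (e.g.
coplanar) direction sets fail early.  A scheme must contain at least one
b=0 volume and seven diffusion-weighted volumes — the identifiability
minimum for the seven parameters.

**LLS** is ordinary least squares of log-signals.  Signals ≤ 0 (possible
after magnitude noise plus dropout) are clamped to machine-epsilon times
the voxel's maximum signal before the log; affected voxels are flagged.
All-zero voxels yield a zero tensor plus a flag rather than an exception.

**WLLS** is a fixed two-pass scheme: pass 1 is LLS; pass 2 solves weighted
least squares with weights equal to the squared *predicted* pass-1 signals,
`w_i = exp(2 X_i β_LLS)`.  Predicted rather than observed weights are used
because observed weights are correlated with the noise they are meant to
correct for.  This undoes the heteroscedasticity created by the log
transform (log-noise variance scales as 1/S²).

**NLLS** minimizes the raw-signal residual sum of squares by damped
Gauss-Newton with a Levenberg–Marquardt damping schedule (damping ×10 on a
rejected step, ÷10 on an accepted one), initialized at the LLS solution.
Convergence is declared when the relative parameter change falls below
1e-8, with a 100-iteration cap; non-converged voxels revert to the LLS
estimate and are flagged (because steps are only ever accepted when they
reduce the objective, the returned objective never exceeds the
initialization's).  The constrained variant (`nlls-pos`) parameterizes
`D = L Lᵀ` through its Cholesky factor, so the estimate is positive
semidefinite by construction; it is initialized from the PSD projection of
the LLS tensor.  All solvers are batched over voxels with dense numpy
linear algebra; the per-iteration cost is one model evaluation, one
Jacobian, and a batched 7×7 solve.

**RESTORE** is robust iteratively-reweighted NLLS with outlier rejection.
Per voxel: (1) initial NLLS; (2) if every absolute residual is within
3σ the NLLS result is accepted unchanged (the early-accept path is exact,
not approximate); otherwise (3) iteratively reweighted NLLS with
Geman–McClure weights `w_i = 1/(r_i² + C²)`, `C = 1.4826 median|r|`
recomputed each iteration, until the normalized weights move by less than
1e-6 or 50 iterations; (4) measurements with `|r_i| > 3σ` are flagged as
outliers and excluded, and the voxel is refit by unweighted NLLS on the
remainder; (5) if fewer than `max(7, n_dwi/2)` diffusion-weighted
measurements (or no b0) survive, the voxel falls back to WLLS and is
flagged.  Diagnostics record the full per-voxel, per-volume outlier mask.

σ is the acquisition's Gaussian noise SD, passed explicitly or estimated
(`sigma="auto"`): with repeated b0 volumes, the SD of consecutive b0
differences divided by √2, pooled over a high-signal mask; with a single
b0, 1.4826 × the median absolute LLS residual in the signal domain.  A
floor of 1e-6 × the mean high-signal b0 is applied so that exactly
noiseless data (where σ̂ = 0 and every residual is a rounding error) take
the early-accept path instead of rejecting everything.

**FA** is computed from the eigendecomposition with negative eigenvalues
clamped to zero first and the result clipped to [0, 1]; a zero spectrum
maps to FA = 0.  The unclamped spectrum is kept alongside.  On-disk tensor
maps use the FSL lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz),
re-ordered from the internal layout.

## Group statistics

The analysis order is fit → FA → Gaussian smoothing → WM mask → statistics.
Smoothing is mask-normalized (`smooth(map·mask)/smooth(mask)`), isotropic
in physical units (default σ = 3 mm, truncated at 4 SD), so constants are
preserved and zeros outside the mask do not bleed in.  The WM mask keeps
voxels whose mean FA across subjects strictly exceeds 0.20; each fit
variant gets its own mask, while the cross-fit ICC uses a shared mask from
the pooled mean (an interpretive choice; a shared mask for the per-fit
statistics is available by passing one explicitly).

ANCOVA η²ₚ uses effect coding for the three-level group factor with
Type-III sums of squares (full model versus the model without the group
columns), which is order-independent under the unbalanced group sizes;
η²ₚ = SS_group/(SS_group + SS_residual).  A constant covariate (e.g. a
single-gender cohort) is dropped with a warning rather than an error.

Hedges' *g* is covariate-adjusted by default: `FA ~ group + age + gender`
on the two groups, `g = J·β_group/√MS_residual` with
`J = 1 − 3/(4(n₁+n₂) − 9)` (the small-sample correction uses the raw group
sizes, not covariate-adjusted degrees of freedom — the difference is
undetectable at these n).  Sign convention: first-listed group minus
second, so an (AD, HC) pair is negative where AD is lower.  A raw
(unadjusted) variant is available by flag.  Residual sums of squares at
rounding level (identical groups) map to g = 0 rather than an unstable
ratio.

Partial Spearman correlations rank-transform FA and score (average ranks on
ties), residualize both rank vectors on [1, age, gender], and correlate the
residuals.  Missing scores are dropped pairwise per score, maximizing n,
and the exclusion count is recorded.  Constant scores yield ρ = 0 with a
flag.

Bartlett's equal-variance test runs on one scalar per subject (mean WM FA)
per group, as an advisory ANCOVA assumption gate: it is logged, never
aborts.  The scalar choice is an interpretation — a single test statistic
per comparison implies a subject-level summary.

Clusters are connected components of the strictly supra-threshold set
(two-sided for g and ρ with signs kept separate, one-sided for η²ₚ),
under 6/18/26-connectivity (default 26); components survive only when
size > min (strict, default 100 voxels).  Atlas labeling reports, per
intersected region, the percentage of the region covered and of the
cluster contained.  Effect-size thresholds are conventions for "large",
not calibrated tests; the null behavior of the thresholded maps is checked
empirically on effect-free phantom contrasts rather than assumed.

Maps of the same kind and contrast can be averaged voxelwise across fits
(and acquisitions) before thresholding, giving the more robust combined
comparison; the region-by-contrast coverage summary is computed from the
averaged maps.

## Consistency across fits

ICC(3,1) — two-way mixed, fits fixed, subjects random, single-measure,
consistency form — is computed per voxel on the subjects × variants FA
matrix:

    ICC(3,1) = (MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error).

The consistency (not absolute-agreement) form follows the "(3,1)"
designation and ignores additive offsets between fits.  Degenerate voxels
(zero total variance) are excluded from the WM mean rather than
zero-filled, which would bias it.  The leave-one-out sweep reports, per
left-out variant, the change in mean WM r-ICC and the correlation between
full and reduced ICC maps; a variant whose removal *raises* the mean is
inconsistent with the rest.  Cross-fit r² matrices correlate per-region
cluster volumes and effect sizes across variant pairs, with regions absent
from a variant counted as zero.

## The synthetic cohort

The generator emulates what the analysis assumes about real cohorts, not
the MR physics of any scanner.

*Geometry.*  One common grid for all subjects (registration and template
construction are out of scope by design — grids are enforced equal, never
resampled).  Default 24×24×12 voxels of 2 mm: a "fornix-like" ellipsoidal
tract (FA ≈ 0.80, eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s, ~600 voxels)
embedded in a box-shaped WM shell (FA ≈ 0.45, (1.2, 0.55, 0.55)×10⁻³) that
keeps the 0.20 mask threshold non-trivially exercised, on near-isotropic
background (FA ≈ 0.06).  ROIs must not overlap (ambiguous ground truth is
an error); the shell declares the tract as an exclusion so the two nest.

*Acquisitions.*  Three single-shell presets at b = 1000 s/mm²: 30
directions + 1 b0 (n = 38/23/7), 48 + 6 (n = 41/20/12), and 54 + 7
(n = 80/36/11), with b0 volumes leading.  Directions are a deterministic
spherical-Fibonacci hemisphere set — reproducible without an iterative
electrostatic solver and adequately uniform from ~30 directions up
(pairwise minimum angle > 10° at n = 48, verified by test).  An optional
seeded rotation re-orients the whole set without changing its geometry.

*Variability.*  Eigenvalue variability is fractional and split into a
per-subject scalar (default SD 4%) and a per-subject smooth spatial field
(default SD 8%, correlation length 1.5 voxels, one field per eigenvalue
channel).  The split matters: with a single latent tensor per ROI per
subject, any chance correlation between a subject-level draw and a
covariate turns into an ROI-spanning coherent artifact in adjusted group
maps — uniform-ROI phantoms overstate that failure mode badly.  The smooth
field restores within-tract heterogeneity, so chance fluctuations stay
local and fall under the 100-voxel cluster floor, while real group effects
(coherent across subjects) survive.

*Group effects.*  A group effect multiplies (λ1 − λ2) in a chosen ROI,
lowering FA at constant λ2, λ3.  The default AD deficit is calibrated so
the *true* standardized effect (FA decrement over the total true-FA SD
under jitter) equals 1.5, matching the magnitude such studies report for
the fornix; the factor is solved by bisection against a fixed-seed Monte
Carlo estimate of the jitter-induced FA SD.  MCI has no built-in effect,
making HC-vs-MCI the pipeline's null contrast.  The observed effect after
noise and smoothing differs somewhat from the true target (smoothing
attenuates both the effect at ROI edges and the within-ROI variability).

*Noise and artifacts.*  Rician magnitude noise `sqrt((S+n₁)² + n₂²)` at a
default b0 SNR of 25 (no published SNR exists for these scanners; 25 is a
typical clinical single-shell value, and results can be regenerated at any
SNR).  Signal dropout corrupts whole (DWI volume × axial slice) blocks —
the footprint of motion/pulsation artifacts that robust fitting targets —
each with probability 1% at a 0.3 amplitude factor; b0 volumes are never
corrupted, and the corrupted positions are recorded as ground truth for
outlier-detection scoring.

*Covariates and scores.*  Ages, gender proportions, and MoCA/MMSE/ADAS
group means and SDs are calibrated to the published demographics of the
three acquisitions.  A subject's score is its group target mean plus a
slope times the subject's deviation in mean ROI true FA, plus Gaussian
noise; the slope is the least-squares line through the (expected group ROI
FA, group score target) pairs.  Group means therefore match the targets in
expectation while the score stays monotonically coupled to FA with known
sign (MMSE/MoCA positive, ADAS negative), which is what the Spearman stage
needs to be testable.

*Reproducibility.*  Every random draw derives from the single spec seed via
`SeedSequence(seed, spawn_key=(subject_index, stage))` with fixed stage
numbers for tensors, covariates, outliers, noise, and scores — partial
re-runs and subject-order changes cannot shift other subjects' draws.

*What the phantom does not model* — and what passing tests therefore do
not show about real data: crossing fibers and multi-compartment diffusion,
susceptibility/eddy-current distortion, inter-scanner bias fields,
registration error (the common-grid assumption), realistic anatomy beyond
the three-compartment geometry, and spatially correlated physiological
noise beyond block dropout.

## Problem sizes

Defaults were chosen so a full experiment is a desk-scale computation: the
73-subject, five-variant default cohort runs in minutes on one CPU, and the
test suite's full-scale checks (consistency band, end-to-end detection)
reuse a single such run.  The null-contrast replication uses five cohort
seeds with the two linear fit variants — the nullness of an effect-free
contrast is a property of the statistics stage, not of the fit family — and
the Monte-Carlo studies (RESTORE robustness, WLLS precision) use 200–500
voxel replicates, enough to separate the compared quantities by well more
than their simulation error.

## Known limitations

- The RESTORE constants (3σ cutoff, Geman–McClure weights, minimum retained
  count) follow the standard robust-fitting recipe; tool-specific defaults
  of external packages are not reproduced, so the five variants represent
  algorithm families, not particular software products.
- WLLS implements one weight convention (predicted squared signals); other
  tools' conventions may differ in ways not resolvable from published
  descriptions.
- b-vectors are taken in the image frame as stored; gradient-frame rotation
  compensation belongs to preprocessing, which is out of scope.
- The voxelwise ICC construction (subjects × fits per voxel, averaged over
  WM) is one reading of a summary-level description; alternatives (e.g.
  whole-brain pooling) would change the reported mean but not the ranking
  of variants.
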