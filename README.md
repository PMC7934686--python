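# dtifitlab

Diffusion-tensor fitting-algorithm comparison for fractional-anisotropy (FA)
group analysis.

White-matter microstructure studies in aging cohorts — healthy controls
(HC), mild cognitive impairment (MCI), Alzheimer's disease (AD) — usually
rest on FA maps derived from diffusion tensor imaging.  FA, however, depends
on how the tensor is fit.  This package implements the four regression
families behind the common tools (ordinary linear least squares on
log-signals, two-pass weighted linear least squares, non-linear least
squares with optional positivity constraint, and robust RESTORE outlier
rejection), the voxel-based effect-size statistics used to compare the
groups, and the agreement analysis that quantifies how much the choice of
fit matters.  Because clinical diffusion data are access-restricted, the
package ships a synthetic-cohort generator with known tensor ground truth
that emulates the statistical structure of such a study, so every stage can
be validated end to end.

It is intended for diffusion-MRI methods researchers who want a tested,
reproducible re-implementation of a multi-fit FA group pipeline, and for
anyone needing a ground-truth DWI phantom with group effects, covariates,
Rician noise, and signal-dropout artifacts.

## The model

Every fit inverts the Stejskal–Tanner signal equation per voxel,

    S_i = S0 · exp(−b_i · g_iᵀ D g_i),

where `D` is the 3×3 symmetric diffusion tensor, `b_i` (s/mm²) and `g_i`
the diffusion weighting and unit encoding direction of volume `i`.  With
`λ1 ≥ λ2 ≥ λ3` the eigenvalues of `D`,

    FA = sqrt(3/2) · sqrt(Σ(λ_k − λ̄)²) / sqrt(Σλ_k²).

Group statistics are effect sizes, not p-values: voxelwise ANCOVA partial
eta-squared (η²ₚ, group factor with age and gender covariates, Type-III sums
of squares), post hoc covariate-adjusted Hedges' *g*, and covariate-adjusted
Spearman correlations with cognitive scores (MoCA, MMSE, ADAS).  Clusters
are connected components above strict thresholds (η²ₚ > 0.15, |g| > 0.85,
|ρ| > 0.50, size > 100 voxels) inside a white-matter mask (mean FA > 0.20).
Cross-fit agreement is the intraclass correlation ICC(3,1) — fits as fixed
raters, subjects random, consistency form — averaged over the WM mask, plus
a leave-one-fit-out sweep.

## Worked example

```python
from dtifitlab import (RunConfig, run_experiment, default_phantom_spec,
                       AnalysisConfig)

spec = default_phantom_spec("GE48", seed=7, dims=(16, 16, 8),
                            n_per_group={"HC": 10, "MCI": 8, "AD": 8})
config = RunConfig(phantom=spec, variants=["lls", "wlls", "nlls"],
                   analysis=AnalysisConfig(min_cluster_voxels=20))
report = run_experiment(config)

print(f"mean WM r-ICC: {report.consistency['mean_r_icc']:.3f}")
for variant, res in report.per_fit.items():
    c = res["clusters"]["AD_vs_HC"][0]
    region, pct_region, _ = c.label_overlaps[0]
    print(f"{variant:5s} AD vs HC: {c.size} voxels, peak g = {c.peak_value:+.2f}, "
          f"covers {pct_region:.0f}% of {region}")
print("HC vs MCI clusters:", len(report.combined["clusters"]["HC_vs_MCI"]))
```

prints

```
mean WM r-ICC: 0.970
lls   AD vs HC: 295 voxels, peak g = -3.11, covers 71% of fornix
wlls  AD vs HC: 214 voxels, peak g = -2.72, covers 71% of fornix
nlls  AD vs HC: 172 voxels, peak g = -2.76, covers 68% of fornix
HC vs MCI clusters: 0
```

Reading: the three fit variants agree almost perfectly on how they rank
subjects (r-ICC 0.97, "excellent" agreement); the AD group's built-in FA
deficit in the fornix-like tract is found by every variant as a large
negative-*g* cluster covering ~70% of the tract; and the contrast with no
built-in effect (HC vs MCI) stays empty.

The same pipeline is available from the shell:

```sh
dtifitlab phantom  --out cohort/ --seed 7          # write DWI + tables
dtifitlab fit      --dwi cohort/dwi/HC001.nii.gz --bval cohort/dwi/HC001.bval \
                   --bvec cohort/dwi/HC001.bvec --method restore --out-fa fa.nii.gz
dtifitlab run-all  --out run/ --seed 7             # the full experiment
```

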