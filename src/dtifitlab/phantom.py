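"""Synthetic multi-group DWI cohorts with known tensor ground truth.

The generator emulates the statistical structure a voxel-based FA group
analysis assumes: a common grid for all subjects (no registration), a small
set of anatomically flavored ROIs (a high-anisotropy "fornix-like" tract
embedded in a moderate-anisotropy white-matter shell, surrounded by
near-isotropic background), per-subject eigenvalue jitter, group effects
expressed as a shrinkage of (lambda1 - lambda2) in chosen ROIs, covariates
and cognitive scores calibrated to a published three-group aging cohort,
sporadic volume-by-slice signal dropout (the artifact class robust fitting
targets), and Rician magnitude noise.

Everything is reproducible from a single integer seed: per-subject,
per-stage random streams are derived with ``np.random.SeedSequence(seed,
spawn_key=(subject_index, stage))`` so partial re-runs stay deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .fit import fa_from_eigenvalues, matrix_to_tensor
from .io import (
    CohortTable,
    DWIVolume,
    GradientScheme,
    LabelAtlas,
    ValidationError,
)

import pandas as pd

__all__ = [
    "ROIDef",
    "GroupEffect",
    "GroupCovariates",
    "ScoreModel",
    "PhantomSpec",
    "GroundTruth",
    "make_scheme",
    "tensor_from_eigen",
    "predict_signal",
    "add_rician_noise",
    "inject_outliers",
    "generate_cohort",
    "default_phantom_spec",
    "effect_factor_for_target_g",
    "ACQUISITION_PRESETS",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# stage tags for the counter-based seed derivation
_STAGE_TENSOR, _STAGE_COVAR, _STAGE_OUTLIER, _STAGE_NOISE, _STAGE_SCORE = range(5)


# --------------------------------------------------------------------------
# low-level building blocks
# --------------------------------------------------------------------------


def make_scheme(
    n_directions: int,
    n_b0: int,
    bval: float = 1000.0,
    seed: int | None = None,
) -> GradientScheme:
    """Gradient scheme: ``n_b0`` b=0 volumes first, then ``n_directions``
    quasi-uniform unit vectors on the upper hemisphere.

    Directions come from a deterministic spherical-Fibonacci lattice (no
    iterative electrostatic solver; adequate uniformity for n >= 30).  When a
    seed is given the whole set is additionally rotated by a random rotation,
    which changes nothing about its uniformity.
    """
    if n_directions < 7:
        raise ValidationError(
            "at least 7 diffusion directions are required; "
            "the tensor is unidentifiable below that"
        )
    if n_b0 < 1:
        raise ValidationError("at least one b=0 volume is required")
    i = np.arange(n_directions)
    z = (i + 0.5) / n_directions  # upper hemisphere
    phi = i * _GOLDEN_ANGLE
    rho = np.sqrt(1.0 - z * z)
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    if seed is not None:
        rng = np.random.default_rng(seed)
        # QR of a Gaussian matrix gives a Haar-random rotation
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        dirs = dirs @ q.T
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def tensor_from_eigen(
    eigenvalues: np.ndarray, principal_dir: np.ndarray
) -> np.ndarray:
    """Symmetric 6-vector tensor with the given (sorted, positive) spectrum
    and its leading eigenvector along ``principal_dir``.

    The lambda2/lambda3 eigenvectors complete the basis deterministically
    (Gram-Schmidt against the least-aligned coordinate axis).
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    if lam.shape != (3,):
        raise ValidationError("eigenvalues must be a 3-vector")
    if not (lam[0] >= lam[1] >= lam[2] > 0):
        raise ValidationError(
            f"eigenvalues must satisfy lam1 >= lam2 >= lam3 > 0, got {lam}"
        )
    V = _basis_from_dir(principal_dir)
    D = V @ np.diag(lam) @ V.T
    return matrix_to_tensor(D)


def _basis_from_dir(principal_dir) -> np.ndarray:
    """Orthonormal basis with the given direction as its first column."""
    v1 = np.asarray(principal_dir, dtype=float).ravel()
    n = np.linalg.norm(v1)
    if n == 0:
        raise ValidationError("principal direction must be non-zero")
    v1 = v1 / n
    helper = np.zeros(3)
    helper[np.argmin(np.abs(v1))] = 1.0
    v2 = helper - np.dot(helper, v1) * v1
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    return np.column_stack([v1, v2, v3])


def predict_signal(
    tensor: np.ndarray, scheme: GradientScheme, s0: float = 1.0
) -> np.ndarray:
    """Noise-free Stejskal-Tanner signals, one per volume.

    ``S_i = s0 exp(-b_i g_i^T D g_i)``; b=0 volumes return exactly s0.
    """
    from .fit import tensor_to_matrix

    D = tensor_to_matrix(np.asarray(tensor, dtype=float))
    g = scheme.bvecs
    quad = np.einsum("ni,ij,nj->n", g, D, g)
    return float(s0) * np.exp(-scheme.bvals * quad)


def add_rician_noise(
    signals: np.ndarray,
    sigma: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rician magnitude noise: ``sqrt((S + n1)^2 + n2^2)`` with n1, n2
    independent N(0, sigma).  ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    S = np.asarray(signals, dtype=float)
    if sigma == 0:
        return S.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n1 = rng.normal(0.0, sigma, size=S.shape)
    n2 = rng.normal(0.0, sigma, size=S.shape)
    return np.sqrt((S + n1) ** 2 + n2**2)


def inject_outliers(
    volume: DWIVolume,
    rate: float,
    dropout_factor: float = 0.3,
    seed: int | np.random.Generator = 0,
):
    """Corrupt random (DWI volume x axial slice) blocks by a signal dropout.

    Each diffusion-weighted volume/slice pair is corrupted independently
    with probability ``rate``; corrupted signals are multiplied by
    ``dropout_factor``.  b=0 volumes are never corrupted.  Returns the
    corrupted DWIVolume and a boolean mask (same shape as the signal) of the
    corrupted positions.
    """
    if not (0 <= rate < 0.5):
        raise ValidationError("outlier rate must lie in [0, 0.5)")
    if not (0 <= dropout_factor < 1):
        raise ValidationError("dropout factor must lie in [0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    signal = volume.signal.copy()
    mask = np.zeros(signal.shape, dtype=bool)
    nz = signal.shape[2]
    dwi_idx = np.flatnonzero(volume.scheme.dwi_mask)
    hit = rng.random((dwi_idx.size, nz)) < rate
    for vi, vol in enumerate(dwi_idx):
        for sl in np.flatnonzero(hit[vi]):
            signal[:, :, sl, vol] *= dropout_factor
            mask[:, :, sl, vol] = True
    out = DWIVolume(
        signal=signal,
        voxel_size=volume.voxel_size,
        scheme=volume.scheme,
        subject_id=volume.subject_id,
        affine=volume.affine,
    )
    return out, mask


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------


@dataclass
class ROIDef:
    """Region with uniform baseline tensor.

    ``kind`` is ``box`` (``size`` = half-extents, voxels) or ``ellipsoid``
    (``size`` = semi-axes, voxels).  ``exclude`` lists ROI names carved out
    of this mask, which lets a shell surround an embedded tract without the
    two overlapping.
    """

    name: str
    kind: str
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    eigenvalues: tuple[float, float, float]  # mm^2/s, sorted descending
    principal_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)
    exclude: tuple[str, ...] = ()

    def base_mask(self, dims) -> np.ndarray:
        ii = np.indices(dims).astype(float)
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.size, dtype=float)
        if self.kind == "box":
            return np.all(
                np.abs(ii - c[:, None, None, None]) <= s[:, None, None, None],
                axis=0,
            )
        if self.kind == "ellipsoid":
            d = (ii - c[:, None, None, None]) / s[:, None, None, None]
            return np.sum(d * d, axis=0) <= 1.0
        raise ValidationError(f"unknown ROI kind {self.kind!r}")


@dataclass
class GroupEffect:
    """Multiplicative factor on (lambda1 - lambda2) for one ROI and group.

    Factors below 1 reduce anisotropy (lambda1 is pulled toward lambda2),
    lowering true FA in that group's ROI.
    """

    roi: str
    group: str
    factor: float


@dataclass
class GroupCovariates:
    age_mean: float
    age_sd: float
    female_prop: float


@dataclass
class ScoreModel:
    """Cognitive score coupled monotonically to true ROI FA.

    A subject's score is ``group mean + slope * (subject ROI FA - expected
    group ROI FA) + N(0, sd)`` where the slope is the least-squares line
    through the (group expected FA, group target mean) pairs, so group means
    match the targets in expectation and the Spearman sign is known.
    """

    name: str
    group_means: dict[str, float]
    sd: float


@dataclass
class PhantomSpec:
    """Full description of a synthetic cohort.

    Eigenvalue variability has two components, both fractional: a
    per-subject scalar jitter (``between_subject_sd``, biological
    between-subject differences, spatially coherent within an ROI) and a
    per-subject smooth spatial field (``within_roi_sd``, correlation length
    ``field_smooth_vox`` voxels, within-tract heterogeneity).  Splitting the
    two keeps chance subject-level fluctuations from appearing as
    ROI-spanning coherent effects, which uniform-ROI phantoms overstate.
    ``snr`` is the b0 signal-to-noise ratio S0/sigma of the Rician noise.
    """

    dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    rois: list[ROIDef] = field(default_factory=list)
    group_effects: list[GroupEffect] = field(default_factory=list)
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 41, "MCI": 20, "AD": 12}
    )
    between_subject_sd: float = 0.04
    within_roi_sd: float = 0.08
    field_smooth_vox: float = 1.5
    snr: float = 25.0
    s0: float = 1000.0
    outlier_rate: float = 0.01
    dropout_factor: float = 0.3
    scheme_spec: tuple[int, int, float] = (48, 6, 1000.0)
    background_eigenvalues: tuple[float, float, float] = (
        0.80e-3,
        0.72e-3,
        0.72e-3,
    )
    covariates: dict[str, GroupCovariates] = field(default_factory=dict)
    scores: list[ScoreModel] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for roi in self.rois:
            lam = roi.eigenvalues
            if not (lam[0] >= lam[1] >= lam[2] > 0):
                raise ValidationError(
                    f"ROI {roi.name!r}: eigenvalues must be sorted positive"
                )
        for eff in self.group_effects:
            if eff.factor <= 0:
                raise ValidationError("group effect factors must be positive")
        if self.snr <= 0:
            raise ValidationError("snr must be positive")
        if not (0 <= self.outlier_rate < 0.5):
            raise ValidationError("outlier_rate must lie in [0, 0.5)")


@dataclass
class GroundTruth:
    """Per-subject generating tensors, true FA, and corruption bookkeeping."""

    tensors: np.ndarray  # (n_subjects, nx, ny, nz, 6)
    true_fa: np.ndarray  # (n_subjects, nx, ny, nz)
    outlier_masks: np.ndarray  # (n_subjects, nx, ny, nz, nvol) bool
    roi_mean_fa: np.ndarray  # (n_subjects,) mean true FA over effect ROIs


# --------------------------------------------------------------------------
# effect-size calibration
# --------------------------------------------------------------------------


def _apply_factor(lam: np.ndarray, factor: float) -> np.ndarray:
    out = np.array(lam, dtype=float)
    out[0] = out[1] + factor * (out[0] - out[1])
    return out


def effect_factor_for_target_g(
    eigenvalues,
    jitter_sd: float,
    target_g: float,
    n_mc: int = 4000,
    seed: int = 987654321,
) -> float:
    """(lambda1-lambda2) factor whose true-FA decrement equals
    ``|target_g|`` true-FA standard deviations.

    ``jitter_sd`` is the total fractional eigenvalue variability (combined
    subject-level and within-ROI components, added in quadrature).  The FA
    SD it induces is estimated by a fixed-seed Monte Carlo; the factor is
    then solved by bisection on the (monotone) FA-versus-factor curve.  The
    target is the *true* standardized effect; the observed effect after
    noise and smoothing differs somewhat.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    rng = np.random.default_rng(seed)
    jit = lam[None, :] * (
        1.0 + rng.normal(0.0, jitter_sd, size=(n_mc, 3))
    )
    jit = np.sort(np.abs(jit), axis=1)[:, ::-1]
    sd_fa = float(np.std(fa_from_eigenvalues(jit), ddof=1))
    fa0 = float(fa_from_eigenvalues(lam))
    target_fa = fa0 - abs(target_g) * sd_fa
    if target_fa <= 0:
        raise ValidationError("target effect exceeds the attainable FA range")

    def f(factor):
        return float(fa_from_eigenvalues(_apply_factor(lam, factor))) - target_fa

    return float(brentq(f, 1e-6, 1.0, xtol=1e-10))


# --------------------------------------------------------------------------
# published-cohort presets (three single-shell acquisitions)
# --------------------------------------------------------------------------

#: demographics and cognitive-score calibration per acquisition: group sizes,
#: age mean (SD), female fraction, and MMSE/MoCA/ADAS group means (SD).
ACQUISITION_PRESETS = {
    "SI30": {
        "scheme_spec": (30, 1, 1000.0),
        "n_per_group": {"HC": 38, "MCI": 23, "AD": 7},
        "covariates": {
            "HC": GroupCovariates(70.1, 4.0, 25 / 38),
            "MCI": GroupCovariates(70.9, 8.1, 14 / 23),
            "AD": GroupCovariates(75.9, 8.6, 3 / 7),
        },
        "scores": [
            ScoreModel("MMSE", {"HC": 29.4, "MCI": 28.3, "AD": 19.6}, 2.5),
            ScoreModel("MoCA", {"HC": 25.7, "MCI": 22.5, "AD": 12.6}, 3.5),
            ScoreModel("ADAS", {"HC": 8.6, "MCI": 11.7, "AD": 23.1}, 3.3),
        ],
    },
    "GE48": {
        "scheme_spec": (48, 6, 1000.0),
        "n_per_group": {"HC": 41, "MCI": 20, "AD": 12},
        "covariates": {
            "HC": GroupCovariates(70.8, 5.8, 27 / 41),
            "MCI": GroupCovariates(72.7, 9.3, 9 / 20),
            "AD": GroupCovariates(75.6, 5.4, 2 / 12),
        },
        "scores": [
            ScoreModel("MMSE", {"HC": 29.3, "MCI": 27.3, "AD": 23.7}, 1.6),
            ScoreModel("MoCA", {"HC": 25.4, "MCI": 21.4, "AD": 16.1}, 3.1),
            ScoreModel("ADAS", {"HC": 8.5, "MCI": 14.6, "AD": 22.2}, 4.6),
        ],
    },
    "SI54": {
        "scheme_spec": (54, 7, 1000.0),
        "n_per_group": {"HC": 80, "MCI": 36, "AD": 11},
        "covariates": {
            "HC": GroupCovariates(69.6, 6.2, 56 / 80),
            "MCI": GroupCovariates(71.7, 6.5, 18 / 36),
            "AD": GroupCovariates(72.1, 9.2, 3 / 11),
        },
        "scores": [
            ScoreModel("MMSE", {"HC": 28.9, "MCI": 27.3, "AD": 24.1}, 2.2),
            ScoreModel("MoCA", {"HC": 25.3, "MCI": 21.6, "AD": 17.6}, 2.8),
            ScoreModel("ADAS", {"HC": 8.5, "MCI": 12.6, "AD": 19.4}, 3.5),
        ],
    },
}

_FORNIX_EIGS = (1.7e-3, 0.3e-3, 0.3e-3)  # FA ~ 0.80
_WM_SHELL_EIGS = (1.2e-3, 0.55e-3, 0.55e-3)  # FA ~ 0.45


def default_phantom_spec(
    acquisition: str = "GE48",
    seed: int = 0,
    target_g: dict[str, float] | None = None,
    **overrides,
) -> PhantomSpec:
    """The study-condition phantom: a fornix-like high-FA tract embedded in
    a WM shell above the 0.20 mask threshold, near-isotropic background, and
    an AD FA deficit of true standardized magnitude ~1.5 in the tract.

    ``acquisition`` selects the scheme and demographic calibration
    (``SI30``/``GE48``/``SI54``); ``target_g`` maps group -> target
    standardized FA effect in the fornix-like ROI (default ``{"AD": -1.5}``,
    no MCI effect).
    """
    preset = ACQUISITION_PRESETS[acquisition]
    if target_g is None:
        target_g = {"AD": -1.5}
    dims = overrides.pop("dims", (24, 24, 12))
    between_sd = overrides.pop("between_subject_sd", 0.04)
    cx, cy, cz = (dims[0] - 1) / 2, (dims[1] - 1) / 2, (dims[2] - 1) / 2
    within_sd = overrides.pop("within_roi_sd", 0.08)
    rois = [
        ROIDef(
            name="fornix",
            kind="ellipsoid",
            center=(cx, cy, cz),
            size=(7.0 * dims[0] / 24, 5.0 * dims[1] / 24, 4.0 * dims[2] / 12),
            eigenvalues=_FORNIX_EIGS,
            principal_dir=(1.0, 0.0, 0.0),
        ),
        ROIDef(
            name="wm_shell",
            kind="box",
            center=(cx, cy, cz),
            size=(0.38 * dims[0], 0.38 * dims[1], 0.38 * dims[2]),
            eigenvalues=_WM_SHELL_EIGS,
            principal_dir=(0.0, 1.0, 0.0),
            exclude=("fornix",),
        ),
    ]
    # the target is a standardized effect; the factor follows from the total
    # (between-subject + within-ROI) true-FA variability
    jitter_sd = float(np.hypot(between_sd, within_sd))
    effects = [
        GroupEffect(
            roi="fornix",
            group=group,
            factor=effect_factor_for_target_g(_FORNIX_EIGS, jitter_sd, g),
        )
        for group, g in target_g.items()
        if g != 0
    ]
    kwargs = dict(
        n_per_group=dict(preset["n_per_group"]),
        scheme_spec=preset["scheme_spec"],
        covariates={g: c for g, c in preset["covariates"].items()},
        scores=list(preset["scores"]),
    )
    kwargs.update(overrides)  # explicit overrides win over the preset
    return PhantomSpec(
        dims=dims,
        rois=rois,
        group_effects=effects,
        between_subject_sd=between_sd,
        within_roi_sd=within_sd,
        seed=seed,
        **kwargs,
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


def _rng(seed: int, subject: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subject, stage))
    )


def _build_masks(spec: PhantomSpec):
    by_name: dict[str, np.ndarray] = {}
    for roi in spec.rois:
        m = roi.base_mask(spec.dims)
        for name in roi.exclude:
            if name not in by_name:
                raise ValidationError(
                    f"ROI {roi.name!r} excludes unknown ROI {name!r}"
                )
            m = m & ~by_name[name]
        by_name[roi.name] = m
    total = np.zeros(spec.dims, dtype=int)
    for m in by_name.values():
        total += m
    if np.any(total > 1):
        raise ValidationError("overlapping ROIs: ground truth is ambiguous")
    return by_name


def _score_slopes(spec: PhantomSpec):
    """Least-squares slope of group score targets on expected group ROI FA."""
    effect_rois = {e.roi for e in spec.group_effects} or {
        r.name for r in spec.rois
    }
    roi_by_name = {r.name: r for r in spec.rois}
    groups = list(spec.n_per_group)
    fa_g = {}
    for g in groups:
        vals = []
        for name in effect_rois:
            lam = np.array(roi_by_name[name].eigenvalues)
            for eff in spec.group_effects:
                if eff.roi == name and eff.group == g:
                    lam = _apply_factor(lam, eff.factor)
            vals.append(float(fa_from_eigenvalues(lam)))
        fa_g[g] = float(np.mean(vals))
    x = np.array([fa_g[g] for g in groups])
    slopes = {}
    for score in spec.scores:
        y = np.array([score.group_means[g] for g in groups])
        vx = np.sum((x - x.mean()) ** 2)
        slopes[score.name] = (
            float(np.sum((x - x.mean()) * (y - y.mean())) / vx) if vx > 1e-12 else 0.0
        )
    return fa_g, slopes


def generate_cohort(spec: PhantomSpec):
    """Generate a full synthetic cohort.

    Returns ``(volumes, cohort, ground_truth, atlas)`` where ``volumes`` is a
    list of DWIVolume (one per subject, ordered HC then MCI then AD),
    ``cohort`` the covariate table, ``ground_truth`` the generating tensors /
    true FA / outlier masks, and ``atlas`` labels the ROI masks.
    """
    masks = _build_masks(spec)
    scheme = make_scheme(*spec.scheme_spec)
    roi_by_name = {r.name: r for r in spec.rois}
    effect_rois = sorted({e.roi for e in spec.group_effects}) or sorted(masks)
    fa_g, slopes = _score_slopes(spec) if spec.scores else ({}, {})

    labels = np.zeros(spec.dims, dtype=np.int16)
    names = {}
    for i, roi in enumerate(spec.rois, start=1):
        labels[masks[roi.name]] = i
        names[i] = roi.name
    atlas = LabelAtlas(labels=labels, names=names)

    sigma = spec.s0 / spec.snr
    groups = [g for g in ("HC", "MCI", "AD") if spec.n_per_group.get(g, 0) > 0]
    n_total = sum(spec.n_per_group[g] for g in groups)
    nvol = scheme.n_volumes

    volumes: list[DWIVolume] = []
    rows = []
    gt_tensors = np.zeros((n_total, *spec.dims, 6), dtype=np.float32)
    gt_fa = np.zeros((n_total, *spec.dims), dtype=np.float32)
    gt_out = np.zeros((n_total, *spec.dims, nvol), dtype=bool)
    roi_mean_fa = np.zeros(n_total)

    subj = 0
    for group in groups:
        cov = spec.covariates.get(group, GroupCovariates(70.0, 6.0, 0.5))
        for k in range(spec.n_per_group[group]):
            sid = f"{group}{k + 1:03d}"
            rng_t = _rng(spec.seed, subj, _STAGE_TENSOR)
            rng_c = _rng(spec.seed, subj, _STAGE_COVAR)
            rng_o = _rng(spec.seed, subj, _STAGE_OUTLIER)
            rng_n = _rng(spec.seed, subj, _STAGE_NOISE)
            rng_s = _rng(spec.seed, subj, _STAGE_SCORE)

            # --- per-voxel eigenvalues: subject-level scalar jitter plus a
            # smooth within-ROI heterogeneity field, per eigenvalue channel
            if spec.within_roi_sd > 0:
                white = rng_t.normal(size=(3, *spec.dims))
                fld = np.stack(
                    [gaussian_filter(w, spec.field_smooth_vox) for w in white]
                )
                fld /= fld.reshape(3, -1).std(axis=1)[:, None, None, None]
            else:
                fld = np.zeros((3, *spec.dims))
            signal = np.zeros((*spec.dims, nvol))
            region_fa: dict[str, float] = {}
            bg_mask = np.ones(spec.dims, dtype=bool)
            regions = [
                (roi.name, masks[roi.name], np.array(roi.eigenvalues),
                 roi.principal_dir)
                for roi in spec.rois
            ] + [
                ("__background__", None, np.array(spec.background_eigenvalues),
                 (1.0, 0.0, 0.0))
            ]
            for name, mask, lam, pdir in regions:
                if mask is None:
                    mask = bg_mask
                else:
                    bg_mask &= ~mask
                for eff in spec.group_effects:
                    if eff.roi == name and eff.group == group:
                        lam = _apply_factor(lam, eff.factor)
                lam = lam * (
                    1.0 + rng_t.normal(0.0, spec.between_subject_sd, size=3)
                )
                lam = np.sort(np.abs(lam))[::-1]
                lam = np.maximum(lam, 1e-7 * lam[0])
                # voxel-level modulation (lam_vox: (nvox_roi, 3))
                lam_vox = lam[None, :] * (
                    1.0 + spec.within_roi_sd * fld[:, mask].T
                )
                lam_vox = np.maximum(np.abs(lam_vox), 1e-7 * lam[0])
                V = _basis_from_dir(pdir)
                D_vox = np.einsum("ab,vb,cb->vac", V, lam_vox, V)
                quad = np.einsum("vab,na,nb->vn", D_vox, scheme.bvecs,
                                 scheme.bvecs, optimize=True)
                signal[mask] = spec.s0 * np.exp(-scheme.bvals[None, :] * quad)
                gt_tensors[subj][mask] = matrix_to_tensor(D_vox)
                fa_vox = fa_from_eigenvalues(lam_vox)
                gt_fa[subj][mask] = fa_vox
                region_fa[name] = float(fa_vox.mean())

            vol = DWIVolume(
                signal=signal,
                voxel_size=spec.voxel_size,
                scheme=scheme,
                subject_id=sid,
            )
            if spec.outlier_rate > 0:
                vol, omask = inject_outliers(
                    vol, spec.outlier_rate, spec.dropout_factor, rng_o
                )
                gt_out[subj] = omask
            vol = DWIVolume(
                signal=add_rician_noise(vol.signal, sigma, rng_n),
                voxel_size=spec.voxel_size,
                scheme=scheme,
                subject_id=sid,
            )
            volumes.append(vol)

            mean_fa = float(np.mean([region_fa[n] for n in effect_rois]))
            roi_mean_fa[subj] = mean_fa

            age = float(np.clip(rng_c.normal(cov.age_mean, cov.age_sd), 45, 95))
            gender = int(rng_c.random() < cov.female_prop)
            row = {"id": sid, "group": group, "age": age, "gender": gender}
            for score in spec.scores:
                mu = score.group_means[group] + slopes[score.name] * (
                    mean_fa - fa_g[group]
                )
                row[score.name] = float(rng_s.normal(mu, score.sd))
            rows.append(row)
            subj += 1

    cohort = CohortTable(pd.DataFrame(rows))
    gt = GroundTruth(
        tensors=gt_tensors,
        true_fa=gt_fa,
        outlier_masks=gt_out,
        roi_mean_fa=roi_mean_fa,
    )
    return volumes, cohort, gt, atlas
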