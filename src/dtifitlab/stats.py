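"""Voxel-based group analysis of FA maps.

The analysis chain mirrors a voxel-based effect-size study of a three-group
aging cohort: Gaussian smoothing of FA maps, a white-matter analysis mask
from mean FA, a Bartlett equal-variance gate (advisory), voxelwise ANCOVA
effect sizes (partial eta-squared for the three-level group factor with age
and gender as covariates), post hoc covariate-adjusted Hedges' g for group
pairs, covariate-adjusted Spearman correlations between FA and cognitive
scores, connected-component cluster extraction with strict effect-size and
size thresholds, atlas labeling of clusters, and cross-fit map averaging.

Thresholding is by effect size, not p-values: the cutoffs (eta2p > 0.15,
|g| > 0.85, |rho| > 0.50, size > 100 voxels) are conventional large-effect
bands, read strictly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

from .io import CohortTable, LabelAtlas, ValidationError

__all__ = [
    "AnalysisConfig",
    "StatMap",
    "Cluster",
    "smooth_map",
    "wm_mask",
    "bartlett_gate",
    "ancova_eta2p",
    "hedges_g",
    "partial_spearman",
    "extract_clusters",
    "label_clusters",
    "average_maps",
]


@dataclass
class AnalysisConfig:
    """Thresholds and smoothing parameters of the voxel-based analysis."""

    eta2p_threshold: float = 0.15
    g_threshold: float = 0.85
    rho_threshold: float = 0.50
    min_cluster_voxels: int = 100
    fa_mask_threshold: float = 0.20
    smoothing_sigma_mm: float = 3.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        for name in (
            "eta2p_threshold",
            "g_threshold",
            "rho_threshold",
            "min_cluster_voxels",
            "fa_mask_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.smoothing_sigma_mm < 0:
            raise ValidationError("smoothing_sigma_mm must be non-negative")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError("connectivity must be 6, 18 or 26")


@dataclass
class StatMap:
    """Per-voxel scalar statistic on the cohort grid."""

    data: np.ndarray
    kind: str  # eta2p | g | rho | fa | icc
    contrast: str = ""
    thresholds: dict = field(default_factory=dict)
    mask: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class Cluster:
    """Connected supra-threshold component of a statistic map."""

    voxels: np.ndarray  # (n, 3) int indices
    size: int
    peak_value: float
    peak_voxel: tuple[int, int, int]
    centroid: tuple[float, float, float]
    sign: int = 1
    label_overlaps: list = field(default_factory=list)
    # each overlap entry: (region name, % of region covered, % of cluster in region)


# --------------------------------------------------------------------------
# smoothing and masking
# --------------------------------------------------------------------------


def smooth_map(
    data: np.ndarray,
    sigma_mm: float,
    voxel_size,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-normalized isotropic Gaussian smoothing.

    The kernel SD is ``sigma_mm`` in physical units (converted per axis via
    the voxel size, truncated at 4 SD).  Inside the mask the result is
    ``smooth(data * mask) / smooth(mask)``, which preserves constants and
    avoids bleeding zeros in from outside; voxels outside the mask are zero.
    ``sigma_mm = 0`` is the identity.
    """
    if sigma_mm < 0:
        raise ValidationError("sigma_mm must be non-negative")
    data = np.asarray(data, dtype=float)
    if sigma_mm == 0:
        out = data.copy()
        if mask is not None:
            out[~np.asarray(mask, bool)] = 0.0
        return out
    sigma_vox = sigma_mm / np.asarray(voxel_size, dtype=float)
    if mask is None:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, truncate=4.0)
    m = np.asarray(mask, dtype=float)
    num = ndimage.gaussian_filter(data * m, sigma=sigma_vox, truncate=4.0)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox, truncate=4.0)
    out = np.zeros_like(data)
    inside = m > 0
    out[inside] = num[inside] / den[inside]
    return out


def wm_mask(fa_maps, threshold: float = 0.20) -> np.ndarray:
    """White-matter analysis mask: mean FA across subjects strictly above
    ``threshold``."""
    maps = np.asarray(
        [getattr(m, "fa", m) for m in fa_maps]
        if isinstance(fa_maps, (list, tuple))
        else fa_maps,
        dtype=float,
    )
    if maps.size == 0 or maps.shape[0] == 0:
        raise ValidationError("wm_mask requires at least one FA map")
    return maps.mean(axis=0) > threshold


def bartlett_gate(values_by_group) -> tuple[float, float]:
    """Bartlett's test of equal variance across groups (advisory gate).

    Run on a scalar summary per subject (here: mean WM FA); the result is
    logged as an ANCOVA assumption check, it does not abort the analysis.
    """
    samples = [np.asarray(v, dtype=float) for v in values_by_group]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValidationError("bartlett_gate needs >= 2 groups with n >= 2")
    for s in samples:
        if np.var(s, ddof=1) == 0:
            raise ValidationError("degenerate group with zero variance")
    stat, p = sps.bartlett(*samples)
    return float(stat), float(p)


# --------------------------------------------------------------------------
# voxelwise models
# --------------------------------------------------------------------------


def _stack_to_matrix(fa_stack, mask):
    """(nsub, *spatial) stack + mask -> (nsub, nvox) matrix."""
    arr = np.asarray(fa_stack, dtype=float)
    spatial = arr.shape[1:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValidationError(
            f"mask shape {mask.shape} does not match stack grid {spatial}"
        )
    return arr[:, mask], mask


def _scatter_map(values, mask, fill=0.0):
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = values
    return out


def _covariate_columns(cohort: CohortTable, idx=None):
    df = cohort.table if idx is None else cohort.table.iloc[idx]
    age = df["age"].to_numpy(dtype=float)
    gender = df["gender"].to_numpy(dtype=float)
    if np.isnan(age).any() or np.isnan(gender).any():
        raise ValidationError("age/gender must not be missing")
    cols, names = [], []
    for vec, name in ((age, "age"), (gender, "gender")):
        if np.ptp(vec) == 0:
            warnings.warn(
                f"covariate {name!r} is constant and was dropped from the design"
            )
            continue
        cols.append(vec)
        names.append(name)
    return cols, names


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y after OLS on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return np.sum(R * R, axis=0)


def ancova_eta2p(
    fa_stack,
    cohort: CohortTable,
    mask: np.ndarray | None = None,
    contrast: str = "HC vs MCI vs AD",
) -> StatMap:
    """Voxelwise ANCOVA effect size for the three-level group factor.

    Model: FA ~ group (effect-coded) + age + gender.  The group effect is the
    Type-III sum of squares (full model versus the model without the group
    columns; with effect coding this is order-independent under unbalanced
    groups), and ``eta2p = SS_group / (SS_group + SS_residual)``.
    """
    Y, mask = _stack_to_matrix(fa_stack, mask)
    groups = cohort.table["group"].to_numpy()
    levels = [g for g in ("HC", "MCI", "AD") if (groups == g).any()]
    if len(levels) < 2:
        raise ValidationError("ancova_eta2p needs >= 2 groups")
    for g in levels:
        if (groups == g).sum() < 3:
            raise ValidationError(f"group {g} has fewer than 3 subjects")
    if len(Y) != len(groups):
        raise ValidationError("fa_stack and cohort disagree on subject count")

    # effect coding: last level is the reference (-1 row)
    n = len(groups)
    G = np.zeros((n, len(levels) - 1))
    for j, g in enumerate(levels[:-1]):
        G[groups == g, j] = 1.0
    G[groups == levels[-1], :] = -1.0
    cov_cols, _ = _covariate_columns(cohort)
    X_full = np.column_stack([np.ones(n), G, *cov_cols])
    X_red = np.column_stack([np.ones(n), *cov_cols])

    rss_full = _rss(X_full, Y)
    rss_red = _rss(X_red, Y)
    ss_group = np.maximum(rss_red - rss_full, 0.0)
    denom = ss_group + rss_full
    with np.errstate(invalid="ignore", divide="ignore"):
        eta = np.where(denom > 0, ss_group / denom, 0.0)
    return StatMap(
        data=_scatter_map(eta, mask),
        kind="eta2p",
        contrast=contrast,
        mask=mask,
    )


def hedges_g(
    fa_stack,
    cohort: CohortTable,
    pair: tuple[str, str] = ("AD", "HC"),
    mask: np.ndarray | None = None,
    adjusted: bool = True,
) -> StatMap:
    """Voxelwise small-sample-corrected standardized group difference.

    With ``adjusted=True`` (default) the mean difference is covariate
    adjusted: FA ~ group + age + gender is fit on the two groups and g is
    ``J * beta_group / sqrt(MS_residual)`` with ``J = 1 - 3/(4(n1+n2)-9)``.
    Sign convention: first-listed group minus second, so an (AD, HC) pair
    yields negative g wherever FA is lower in AD.
    """
    a, b = pair
    groups = cohort.table["group"].to_numpy()
    sel = np.isin(groups, [a, b])
    idx = np.flatnonzero(sel)
    ga = groups[idx] == a
    n1, n2 = int(ga.sum()), int((~ga).sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"both groups in {pair} need n >= 2")

    Y, mask = _stack_to_matrix(fa_stack, mask)
    Y = Y[idx]
    cols = [np.ones(len(idx)), ga.astype(float)]
    if adjusted:
        cov_cols, _ = _covariate_columns(cohort, idx)
        cols.extend(cov_cols)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    dof = len(idx) - X.shape[1]
    ms_res = np.sum(R * R, axis=0) / dof
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    # a residual at rounding level (e.g. exactly identical groups) is a
    # degenerate voxel, not an infinite effect
    scale = np.max(np.abs(Y), axis=0)
    floor = (1e-10 * (scale + 1.0)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ms_res > floor, J * beta[1] / np.sqrt(ms_res), 0.0)
    return StatMap(
        data=_scatter_map(g, mask),
        kind="g",
        contrast=f"{a} vs {b}",
        mask=mask,
        thresholds={"J": J, "n1": n1, "n2": n2, "adjusted": adjusted},
    )


def partial_spearman(
    fa_stack,
    scores,
    cohort: CohortTable,
    mask: np.ndarray | None = None,
    score_name: str = "",
) -> StatMap:
    """Voxelwise Spearman correlation between FA and a cognitive score with
    age and gender partialled out.

    FA and score are rank-transformed (average ranks on ties), each rank
    vector is residualized on [1, age, gender], and rho is the Pearson
    correlation of the residuals.  Subjects with a missing score are dropped
    (pairwise deletion).  A constant score yields rho = 0 with a flag.
    """
    scores = np.asarray(scores, dtype=float)
    keep = np.flatnonzero(~np.isnan(scores))
    if keep.size < 4:
        raise ValidationError("partial_spearman needs >= 4 scored subjects")
    Y, mask = _stack_to_matrix(fa_stack, mask)
    Y = Y[keep]
    s = scores[keep]
    diagnostics = {"n_used": int(keep.size), "n_dropped": int(len(scores) - keep.size)}
    if np.ptp(s) == 0:
        diagnostics["constant_score"] = True
        return StatMap(
            data=_scatter_map(np.zeros(Y.shape[1]), mask),
            kind="rho",
            contrast=score_name,
            mask=mask,
            diagnostics=diagnostics,
        )
    ry = sps.rankdata(Y, axis=0, method="average")
    rs = sps.rankdata(s, method="average")
    cov_cols, _ = _covariate_columns(cohort, keep)
    Z = np.column_stack([np.ones(keep.size), *cov_cols])
    beta_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    beta_s, *_ = np.linalg.lstsq(Z, rs, rcond=None)
    ey = ry - Z @ beta_y
    es = rs - Z @ beta_s
    num = ey.T @ es
    den = np.sqrt(np.sum(ey * ey, axis=0) * np.sum(es * es))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    return StatMap(
        data=_scatter_map(rho, mask),
        kind="rho",
        contrast=score_name,
        mask=mask,
        diagnostics=diagnostics,
    )


# --------------------------------------------------------------------------
# clusters
# --------------------------------------------------------------------------

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _components(binary: np.ndarray, connectivity: int):
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    lab, n = ndimage.label(binary, structure=structure)
    return lab, n


def extract_clusters(
    stat_map,
    threshold: float,
    min_size: int = 100,
    two_sided: bool = True,
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected components of the strictly supra-threshold voxel set.

    ``two_sided`` thresholds ``|value| > threshold`` and keeps positive and
    negative components separate (appropriate for g and rho); one-sided is
    for non-negative statistics like eta2p.  Components survive only when
    ``size > min_size`` (strict, matching the "size > 100 voxels" rule);
    output is sorted by size, descending.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if connectivity not in _STRUCTURES:
        raise ValidationError("connectivity must be 6, 18 or 26")
    data = np.asarray(getattr(stat_map, "data", stat_map), dtype=float)
    if data.ndim != 3:
        raise ValidationError("cluster extraction requires a 3D map")

    pieces = [(data > threshold, 1)]
    if two_sided:
        pieces.append((data < -threshold, -1))

    clusters: list[Cluster] = []
    for binary, sign in pieces:
        lab, n = _components(binary, connectivity)
        for comp in range(1, n + 1):
            vox = np.argwhere(lab == comp)
            size = len(vox)
            if size <= min_size:
                continue
            vals = data[tuple(vox.T)]
            peak_i = int(np.argmax(np.abs(vals)))
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=size,
                    peak_value=float(vals[peak_i]),
                    peak_voxel=tuple(int(c) for c in vox[peak_i]),
                    centroid=tuple(float(c) for c in vox.mean(axis=0)),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: (-c.size, -abs(c.peak_value)))
    return clusters


def label_clusters(clusters, atlas: LabelAtlas, grid=None) -> list[Cluster]:
    """Attach atlas-region overlaps to each cluster.

    For every region a cluster intersects the overlap entry records the
    percentage of the region covered by the cluster and the percentage of
    the cluster falling in the region, sorted by region coverage.
    """
    for cluster in clusters:
        if grid is not None and atlas.labels.shape != tuple(grid):
            raise ValidationError("atlas grid does not match the map grid")
        lab_at = atlas.labels[tuple(cluster.voxels.T)]
        overlaps = []
        for label in np.unique(lab_at):
            if label == 0:
                continue
            inter = int((lab_at == label).sum())
            region_n = int((atlas.labels == label).sum())
            overlaps.append(
                (
                    atlas.names[int(label)],
                    100.0 * inter / region_n,
                    100.0 * inter / cluster.size,
                )
            )
        overlaps.sort(key=lambda t: -t[1])
        cluster.label_overlaps = overlaps
    return clusters


def average_maps(maps) -> StatMap:
    """Voxelwise arithmetic mean of same-kind, same-contrast statistic maps.

    Averaging across fits (and acquisitions) gives a more robust group-wise
    comparison; downstream thresholds are applied to the averaged map.
    """
    maps = list(maps)
    if not maps:
        raise ValidationError("average_maps needs at least one map")
    kinds = {m.kind for m in maps}
    if len(kinds) != 1:
        raise ValidationError(f"cannot average maps of mixed kinds {kinds}")
    contrasts = {m.contrast for m in maps}
    if len(contrasts) != 1:
        raise ValidationError(f"cannot average maps of mixed contrasts {contrasts}")
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ValidationError("cannot average maps on different grids")
    data = np.mean([m.data for m in maps], axis=0)
    return StatMap(
        data=data,
        kind=maps[0].kind,
        contrast=maps[0].contrast,
        mask=maps[0].mask,
        thresholds={"averaged_over": len(maps)},
    )
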