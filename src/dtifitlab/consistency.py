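"""Agreement across tensor-fit variants.

The central quantity is the intraclass correlation ICC(3,1): a two-way
mixed model treating fit procedures as fixed effects (the "raters") and
subjects as random effects, single-measure, consistency form,

    ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)

with mean squares from the two-way subjects x raters ANOVA decomposition
(no replication).  The consistency form ignores additive offsets between
raters, which is what "the fits rank subjects identically" means.

Voxelwise, the ratings matrix at a voxel is subjects x fit variants of FA;
the mean ICC over the white-matter mask (the "r-ICC") summarizes a variant
set, and a leave-one-out sweep identifies variants whose removal raises it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "FitStack",
    "ConsistencyReport",
    "icc31",
    "voxelwise_icc",
    "leave_one_out",
    "crossfit_matrices",
]


@dataclass
class FitStack:
    """Per-variant, per-subject FA maps on a common grid.

    ``data`` has shape (n_variants, n_subjects, nx, ny, nz).
    """

    variants: list[str]
    data: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if len(self.variants) < 2:
            raise ValidationError("a fit stack needs >= 2 variants")
        if self.data.shape[0] != len(self.variants):
            raise ValidationError("variant names and data axis 0 disagree")
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("duplicate variant names")

    def drop(self, variant: str) -> "FitStack":
        i = self.variants.index(variant)
        keep = [j for j in range(len(self.variants)) if j != i]
        return FitStack(
            variants=[self.variants[j] for j in keep],
            data=self.data[keep],
            subject_ids=self.subject_ids,
        )


@dataclass
class ConsistencyReport:
    icc_map: np.ndarray
    mean_r_icc: float
    leave_one_out: pd.DataFrame  # variant, delta_mean_r_icc, map_correlation
    volume_r2: pd.DataFrame | None = None
    effect_r2: pd.DataFrame | None = None


def _icc31_ms(Y: np.ndarray):
    """Mean squares of the two-way decomposition; Y is (..., n, k)."""
    n, k = Y.shape[-2], Y.shape[-1]
    grand = Y.mean(axis=(-2, -1), keepdims=True)
    row = Y.mean(axis=-1, keepdims=True)
    col = Y.mean(axis=-2, keepdims=True)
    ss_total = np.sum((Y - grand) ** 2, axis=(-2, -1))
    ss_rows = k * np.sum((row - grand) ** 2, axis=(-2, -1))
    ss_cols = n * np.sum((col - grand) ** 2, axis=(-2, -1))
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_err, ss_total


def icc31(ratings: np.ndarray) -> float:
    """ICC(3,1) of a subjects x raters matrix (no missing cells)."""
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValidationError("ratings must be (>=2 subjects) x (>=2 raters)")
    if np.isnan(Y).any():
        raise ValidationError("ratings contain missing cells")
    ms_rows, ms_err, ss_total = _icc31_ms(Y)
    if ss_total <= 0:
        raise ValidationError("degenerate ratings: zero total variance")
    k = Y.shape[1]
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise ValidationError("degenerate ratings: zero total variance")
    return float((ms_rows - ms_err) / denom)


def voxelwise_icc(stack: FitStack, mask: np.ndarray):
    """Per-voxel ICC(3,1) of the subjects x variants FA matrix.

    Returns ``(icc_map, mean_r_icc)``.  Degenerate voxels (zero total
    variance, e.g. masked-out FA identically zero) are set to NaN and
    excluded from the mean.
    """
    mask = np.asarray(mask, dtype=bool)
    k, n = stack.data.shape[0], stack.data.shape[1]
    Y = stack.data[:, :, mask]  # (k, n, nvox)
    Y = np.moveaxis(Y, [0, 1, 2], [2, 1, 0])  # (nvox, n, k)
    ms_rows, ms_err, ss_total = _icc31_ms(Y)
    denom = ms_rows + (k - 1) * ms_err
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (ms_rows - ms_err) / denom
    bad = (ss_total <= 0) | (denom <= 0) | ~np.isfinite(icc)
    icc = np.where(bad, np.nan, icc)
    icc_map = np.full(mask.shape, np.nan)
    icc_map[mask] = icc
    mean = float(np.nanmean(icc)) if np.any(~bad) else float("nan")
    return icc_map, mean


def leave_one_out(stack: FitStack, mask: np.ndarray) -> pd.DataFrame:
    """Leave-one-variant-out consistency sweep.

    For each variant the voxelwise ICC is recomputed without it; the row
    reports the change in mean r-ICC (reduced minus full; a large positive
    delta flags a variant inconsistent with the rest) and the Pearson
    correlation between the full and reduced ICC maps over valid voxels.
    """
    if len(stack.variants) < 3:
        raise ValidationError("leave_one_out needs >= 3 variants")
    full_map, full_mean = voxelwise_icc(stack, mask)
    rows = []
    for variant in stack.variants:
        red_map, red_mean = voxelwise_icc(stack.drop(variant), mask)
        a, b = full_map[mask], red_map[mask]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 2 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
            corr = float(np.corrcoef(a[ok], b[ok])[0, 1])
        else:
            corr = float("nan")
        rows.append(
            {
                "variant": variant,
                "delta_mean_r_icc": red_mean - full_mean,
                "map_correlation": corr,
            }
        )
    return pd.DataFrame(rows)


def crossfit_matrices(per_fit_results: dict):
    """Pairwise squared Pearson correlations of per-region results across fits.

    ``per_fit_results`` maps variant -> {region -> (cluster volume, effect
    size)}.  Regions absent from a variant count as volume 0 / effect 0.
    Returns ``(volume_r2, effect_r2)`` DataFrames, symmetric with unit
    diagonal; cells are NaN when fewer than two regions are available.
    """
    variants = list(per_fit_results)
    if len(variants) < 2:
        raise ValidationError("crossfit_matrices needs >= 2 variants")
    regions = sorted({r for res in per_fit_results.values() for r in res})
    vol = np.zeros((len(variants), len(regions)))
    eff = np.zeros((len(variants), len(regions)))
    for i, v in enumerate(variants):
        for j, r in enumerate(regions):
            if r in per_fit_results[v]:
                vol[i, j], eff[i, j] = per_fit_results[v][r]

    def r2_matrix(M):
        k = len(variants)
        out = np.full((k, k), np.nan)
        for i in range(k):
            out[i, i] = 1.0
            for j in range(i + 1, k):
                if len(regions) < 2:
                    continue
                xi, xj = M[i], M[j]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                out[i, j] = out[j, i] = r * r
        return pd.DataFrame(out, index=variants, columns=variants)

    return r2_matrix(vol), r2_matrix(eff)
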