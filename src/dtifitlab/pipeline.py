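"""End-to-end experiment orchestration.

One config drives the whole comparison: phantom generation (or loading of
real inputs), tensor fitting by every requested variant, FA computation,
smoothing, white-matter masking, the Bartlett variance gate, voxelwise
ANCOVA effect sizes, post hoc pairwise Hedges' g, covariate-adjusted
Spearman correlations with cognitive scores, cluster extraction and atlas
labeling per fit, cross-fit consistency (ICC, leave-one-out, cross-fit r^2
matrices), and an averaged-map analysis across fits.

Determinism: every random draw derives from the config seed through
counter-based sub-seeds (see :mod:`dtifitlab.phantom`), so identical
config + seed reproduces every output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consistency import FitStack, crossfit_matrices, leave_one_out, voxelwise_icc
from .fit import FIT_VARIANTS, compute_fa, fit_volume
from .io import CohortTable, LabelAtlas, ValidationError, write_map
from .phantom import PhantomSpec, default_phantom_spec, generate_cohort
from .stats import (
    AnalysisConfig,
    StatMap,
    ancova_eta2p,
    average_maps,
    bartlett_gate,
    extract_clusters,
    hedges_g,
    label_clusters,
    partial_spearman,
    smooth_map,
    wm_mask,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_experiment",
    "group_analysis",
    "region_summary",
    "summarize_table3",
]

CONTRASTS = ("ANCOVA", "AD_vs_HC", "AD_vs_MCI", "HC_vs_MCI")
_PAIRS = {
    "AD_vs_HC": ("AD", "HC"),
    "AD_vs_MCI": ("AD", "MCI"),
    "HC_vs_MCI": ("HC", "MCI"),
}


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=default_phantom_spec)
    variants: list[str] = field(
        default_factory=lambda: ["lls", "wlls", "nlls", "nlls-pos", "restore"]
    )
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    contrasts: list[str] = field(default_factory=lambda: list(CONTRASTS))
    scores: list[str] = field(default_factory=lambda: ["MoCA", "MMSE", "ADAS"])
    out_dir: str | None = None
    seed: int | None = None  # overrides phantom.seed when given

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError("at least one fit variant is required")
        unknown = [v for v in self.variants if v not in FIT_VARIANTS]
        if unknown:
            raise ValidationError(f"unknown fit variant(s) {unknown}")
        bad = [c for c in self.contrasts if c not in CONTRASTS]
        if bad:
            raise ValidationError(
                f"unknown contrast(s) {bad}; choose from {list(CONTRASTS)}"
            )
        if self.seed is not None:
            self.phantom = dataclasses.replace(self.phantom, seed=int(self.seed))


@dataclass
class RunReport:
    config_hash: str
    seed: int
    per_fit: dict  # variant -> analysis-result dict
    consistency: dict
    combined: dict  # averaged-map analysis-result dict
    bartlett: dict
    provenance: dict
    fa_smoothed: dict | None = None  # variant -> (nsub, *grid) array
    cohort: CohortTable | None = None
    atlas: LabelAtlas | None = None
    wm_masks: dict | None = None


# --------------------------------------------------------------------------
# hashing / serialization helpers
# --------------------------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "phantom": _jsonable(config.phantom),
            "variants": config.variants,
            "analysis": _jsonable(config.analysis),
            "contrasts": config.contrasts,
            "scores": config.scores,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cluster_record(cluster):
    return {
        "size": cluster.size,
        "peak_value": cluster.peak_value,
        "peak_voxel": list(cluster.peak_voxel),
        "centroid": list(cluster.centroid),
        "sign": cluster.sign,
        "label_overlaps": [
            {"region": r, "pct_region": pr, "pct_cluster": pc}
            for r, pr, pc in cluster.label_overlaps
        ],
    }


# --------------------------------------------------------------------------
# per-fit group analysis
# --------------------------------------------------------------------------


def group_analysis(
    fa_smoothed: np.ndarray,
    cohort: CohortTable,
    cfg: AnalysisConfig,
    atlas: LabelAtlas | None = None,
    mask: np.ndarray | None = None,
    contrasts=CONTRASTS,
    scores=("MoCA", "MMSE", "ADAS"),
) -> dict:
    """Full statistics stage on one stack of (smoothed) FA maps.

    Returns a dict with the WM mask, stat maps and labeled clusters per
    contrast/score.  This function is pure: re-running it on saved FA maps
    reproduces the in-pipeline result.
    """
    if mask is None:
        mask = wm_mask(fa_smoothed, cfg.fa_mask_threshold)
    result: dict = {"wm_mask_voxels": int(mask.sum()), "maps": {}, "clusters": {}}

    def clusterize(stat_map: StatMap, threshold, two_sided):
        clusters = extract_clusters(
            stat_map,
            threshold=threshold,
            min_size=cfg.min_cluster_voxels,
            two_sided=two_sided,
            connectivity=cfg.connectivity,
        )
        if atlas is not None:
            clusters = label_clusters(clusters, atlas)
        return clusters

    if "ANCOVA" in contrasts:
        m = ancova_eta2p(fa_smoothed, cohort, mask)
        result["maps"]["ANCOVA"] = m
        result["clusters"]["ANCOVA"] = clusterize(
            m, cfg.eta2p_threshold, two_sided=False
        )
    for name, pair in _PAIRS.items():
        if name not in contrasts:
            continue
        m = hedges_g(fa_smoothed, cohort, pair, mask)
        result["maps"][name] = m
        result["clusters"][name] = clusterize(m, cfg.g_threshold, two_sided=True)
    for score in scores:
        col = cohort.table[score].to_numpy(dtype=float)
        if np.isnan(col).all():
            continue
        m = partial_spearman(fa_smoothed, col, cohort, mask, score_name=score)
        result["maps"][f"rho_{score}"] = m
        result["clusters"][f"rho_{score}"] = clusterize(
            m, cfg.rho_threshold, two_sided=True
        )
    return result


def region_summary(clusters, atlas: LabelAtlas, stat_map: StatMap) -> dict:
    """Per atlas region: (cluster volume in the region, mean statistic there).

    The volume is the voxel count of significant clusters intersecting the
    region; the effect size is the mean map value over those voxels.
    Regions untouched by any cluster are absent (callers fill zeros).
    """
    out: dict[str, tuple[float, float]] = {}
    for label, name in atlas.names.items():
        region = atlas.labels == label
        vox_total = 0
        values = []
        for cluster in clusters:
            sel = region[tuple(cluster.voxels.T)]
            n = int(sel.sum())
            if n:
                vox_total += n
                values.append(stat_map.data[tuple(cluster.voxels[sel].T)])
        if vox_total:
            out[name] = (float(vox_total), float(np.mean(np.concatenate(values))))
    return out


# --------------------------------------------------------------------------
# the experiment
# --------------------------------------------------------------------------


def run_experiment(config: RunConfig, keep_maps: bool = True) -> RunReport:
    """Run the full pipeline on a synthetic cohort.

    Stage order: phantom -> fits -> FA -> smoothing -> WM mask -> Bartlett
    gate -> ANCOVA eta2p -> post hoc g -> Spearman -> clusters + labels per
    fit -> consistency across fits -> averaged-map analysis.  When
    ``config.out_dir`` is set every stage's outputs are written before the
    next begins.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        for sub in ("maps", "clusters", "consistency"):
            (out_dir / sub).mkdir(parents=True, exist_ok=True)

    volumes, cohort, gt, atlas = generate_cohort(config.phantom)
    grid = volumes[0].grid
    voxel_size = volumes[0].voxel_size
    cfg = config.analysis

    if out_dir:
        cohort.table.to_csv(out_dir / "cohort.csv", index=False)

    # --- fits and smoothed FA maps per variant
    fa_smoothed: dict[str, np.ndarray] = {}
    for variant in config.variants:
        stack = np.empty((len(volumes), *grid))
        for i, vol in enumerate(volumes):
            tf = fit_volume(vol, variant)
            fa = compute_fa(tf).fa
            stack[i] = smooth_map(fa, cfg.smoothing_sigma_mm, voxel_size)
            if out_dir:
                write_map(
                    stack[i], vol, out_dir / "maps" / f"fa_{variant}_{vol.subject_id}.nii.gz"
                )
        fa_smoothed[variant] = stack

    # --- per-fit WM masks and statistics
    per_fit: dict[str, dict] = {}
    wm_masks: dict[str, np.ndarray] = {}
    groups = cohort.table["group"].to_numpy()
    bartlett: dict[str, dict] = {}
    for variant in config.variants:
        mask = wm_mask(fa_smoothed[variant], cfg.fa_mask_threshold)
        wm_masks[variant] = mask
        subj_mean = fa_smoothed[variant][:, mask].mean(axis=1)
        by_group = [subj_mean[groups == g] for g in ("HC", "MCI", "AD")
                    if (groups == g).sum() >= 2]
        try:
            stat, p = bartlett_gate(by_group)
            bartlett[variant] = {"statistic": stat, "p_value": p}
        except ValidationError as exc:  # degenerate groups stay advisory
            bartlett[variant] = {"error": str(exc)}
        per_fit[variant] = group_analysis(
            fa_smoothed[variant], cohort, cfg, atlas, mask,
            contrasts=config.contrasts, scores=config.scores,
        )

    # --- consistency across fits (shared mask: mean FA over all fits)
    consistency: dict = {}
    if len(config.variants) >= 2:
        stack = FitStack(
            variants=list(config.variants),
            data=np.stack([fa_smoothed[v] for v in config.variants]),
            subject_ids=cohort.table["id"].tolist(),
        )
        shared_mask = wm_mask(
            stack.data.reshape(-1, *grid), cfg.fa_mask_threshold
        )
        icc_map, mean_icc = voxelwise_icc(stack, shared_mask)
        consistency["mean_r_icc"] = mean_icc
        consistency["icc_map"] = icc_map
        if len(config.variants) >= 3:
            consistency["leave_one_out"] = leave_one_out(stack, shared_mask)
        fitres = {
            v: region_summary(
                per_fit[v]["clusters"].get("ANCOVA", []),
                atlas,
                per_fit[v]["maps"]["ANCOVA"],
            )
            if "ANCOVA" in per_fit[v]["maps"]
            else {}
            for v in config.variants
        }
        if any(fitres.values()):
            vol_r2, eff_r2 = crossfit_matrices(fitres)
            consistency["volume_r2"] = vol_r2
            consistency["effect_r2"] = eff_r2

    # --- averaged-map analysis across fits
    combined: dict = {"maps": {}, "clusters": {}}
    shared_mask = wm_mask(
        np.concatenate([fa_smoothed[v] for v in config.variants]),
        cfg.fa_mask_threshold,
    )
    first = config.variants[0]
    for key in per_fit[first]["maps"]:
        maps = [per_fit[v]["maps"][key] for v in config.variants
                if key in per_fit[v]["maps"]]
        avg = average_maps(maps)
        combined["maps"][key] = avg
        if key == "ANCOVA":
            thr, two = cfg.eta2p_threshold, False
        elif key.startswith("rho_"):
            thr, two = cfg.rho_threshold, True
        else:
            thr, two = cfg.g_threshold, True
        clusters = extract_clusters(
            avg, thr, cfg.min_cluster_voxels, two, cfg.connectivity
        )
        combined["clusters"][key] = label_clusters(clusters, atlas)

    chash = config_hash(config)
    provenance = {
        "config_hash": chash,
        "seed": config.phantom.seed,
        "version": __version__,
        "n_subjects": len(cohort),
        "grid": list(grid),
        "variants": list(config.variants),
    }
    report = RunReport(
        config_hash=chash,
        seed=config.phantom.seed,
        per_fit=per_fit,
        consistency=consistency,
        combined=combined,
        bartlett=bartlett,
        provenance=provenance,
        fa_smoothed=fa_smoothed if keep_maps else None,
        cohort=cohort,
        atlas=atlas,
        wm_masks=wm_masks,
    )
    if out_dir:
        _write_report(report, out_dir, volumes[0])
    return report


def _write_report(report: RunReport, out_dir: Path, reference) -> None:
    for variant, res in report.per_fit.items():
        for key, m in res["maps"].items():
            write_map(m, reference, out_dir / "maps" / f"{variant}_{key}.nii.gz")
        for key, clusters in res["clusters"].items():
            _cluster_table(clusters).to_csv(
                out_dir / "clusters" / f"{variant}_{key}.tsv", sep="\t", index=False
            )
    for key, m in report.combined["maps"].items():
        write_map(m, reference, out_dir / "maps" / f"combined_{key}.nii.gz")
    for key, clusters in report.combined["clusters"].items():
        _cluster_table(clusters).to_csv(
            out_dir / "clusters" / f"combined_{key}.tsv", sep="\t", index=False
        )
    cons = dict(report.consistency)
    icc_map = cons.pop("icc_map", None)
    if icc_map is not None:
        write_map(np.nan_to_num(icc_map), reference,
                  out_dir / "consistency" / "icc_map.nii.gz")
    loo = cons.pop("leave_one_out", None)
    if loo is not None:
        loo.to_csv(out_dir / "consistency" / "leave_one_out.tsv",
                   sep="\t", index=False)
    for name in ("volume_r2", "effect_r2"):
        m = cons.pop(name, None)
        if m is not None:
            m.to_csv(out_dir / "consistency" / f"{name}.tsv", sep="\t")
    payload = {
        "provenance": report.provenance,
        "bartlett": report.bartlett,
        "consistency": cons,
        "per_fit_clusters": {
            v: {k: [_cluster_record(c) for c in cl]
                for k, cl in res["clusters"].items()}
            for v, res in report.per_fit.items()
        },
        "combined_clusters": {
            k: [_cluster_record(c) for c in cl]
            for k, cl in report.combined["clusters"].items()
        },
    }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _cluster_table(clusters) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters, start=1):
        rows.append(
            {
                "cluster": i,
                "size": c.size,
                "peak_value": c.peak_value,
                "peak_x": c.peak_voxel[0],
                "peak_y": c.peak_voxel[1],
                "peak_z": c.peak_voxel[2],
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "centroid_z": c.centroid[2],
                "regions": "; ".join(
                    f"{r} ({pr:.1f}% of region, {pc:.1f}% of cluster)"
                    for r, pr, pc in c.label_overlaps
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "size", "peak_value", "peak_x", "peak_y", "peak_z",
            "centroid_x", "centroid_y", "centroid_z", "regions",
        ],
    )


def summarize_table3(report: RunReport, atlas: LabelAtlas) -> pd.DataFrame:
    """Region-by-contrast coverage of the averaged-map significant clusters.

    Rows are atlas regions, columns contrasts; each cell is the percentage
    of the region's volume covered by significant clusters of the averaged
    maps.  Zero rows are retained.
    """
    contrasts = [k for k in report.combined["clusters"] if not k.startswith("rho_")]
    region_names = [atlas.names[label] for label in sorted(atlas.names)]
    table = pd.DataFrame(0.0, index=region_names, columns=contrasts)
    for contrast in contrasts:
        for label in sorted(atlas.names):
            region = atlas.labels == label
            region_n = int(region.sum())
            covered = np.zeros_like(region)
            for cluster in report.combined["clusters"][contrast]:
                covered[tuple(cluster.voxels.T)] |= True
            table.loc[atlas.names[label], contrast] = (
                100.0 * int((covered & region).sum()) / region_n if region_n else 0.0
            )
    return table
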