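"""End-to-end drivers for the two experiment workflows.

Experiment 1 (state fatigue): per subject, detrend the BOLD series, build the
unit + six-AMR design from the schedule and the subject's run-boundary
ratings, fit the voxelwise GLM, and extract the fatigue-AMR beta map; then
compare the subject maps between groups (MS - HC, optionally adjusting for
age and education), calibrate a Monte-Carlo cluster-extent threshold for the
analysis grid, and report surviving clusters.

Experiment 2 (trait fatigue): per subject, fit the diffusion tensor, derive
FA, exclude the union of white-matter lesion masks from the analysis domain,
regress FA on the FSS total with age and education as covariates within the
chosen group, and cluster-threshold the FSS t map.

Both drivers are deterministic given the configuration seed, log every
tunable parameter, abort with the failing stage's name, and keep partial
outputs with a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FatigueMapError
from . import io as fio
from .paradigm import RATING_SCALES, EventSchedule, ratings_from_tsv, interpolate_amplitudes
from .glm import (
    BoldDataset,
    HRFParams,
    StatMap,
    build_design_matrix,
    contrast_t,
    detrend_timeseries,
    fit_glm,
    group_difference_map,
)
from .clusters import apply_cluster_threshold, restrict_to_roi, simulate_cluster_null
from .dti import (
    FAMap,
    compute_fa,
    exclude_lesions,
    fa_fatigue_regression,
    fit_tensor,
    read_covariates_tsv,
)
from .io import PipelineConfig

logger = logging.getLogger("fatiguemap")


class StageError(FatigueMapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class ExperimentResult:
    """Artifacts of one driver run."""

    group_map: StatMap
    thresholded: StatMap
    clusters: pd.DataFrame
    k_alpha: int
    manifest: dict = field(default_factory=dict)


def _stage(name, fn, manifest):
    logger.info("stage %s: start", name)
    try:
        out = fn()
    except Exception as exc:
        manifest["failed_stage"] = name
        raise StageError(name, exc) from exc
    manifest.setdefault("stages", []).append(name)
    return out


def _smooth_map(values, mask, fwhm_mm, voxel_size_mm):
    from scipy import ndimage

    if not fwhm_mm:
        return values
    sigma = [fwhm_mm / (np.sqrt(8 * np.log(2)) * v) for v in voxel_size_mm]
    filled = np.where(mask, values, 0.0)
    sm = ndimage.gaussian_filter(filled, sigma)
    norm = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = np.full_like(values, np.nan)
    out[mask] = sm[mask] / np.maximum(norm[mask], 1e-12)
    return out


def run_experiment1(config: PipelineConfig) -> ExperimentResult:
    """State-fatigue workflow on a cohort directory (see synth.make_cohort)."""
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"experiment": 1, "config": vars(config).copy()}
    logger.info("experiment 1 config: %s", manifest["config"])
    hrf = HRFParams(shape=config.hrf_shape, scale_s=config.hrf_scale_s)

    covars = _stage("covariates", lambda: read_covariates_tsv(cohort / "covars.tsv"),
                    manifest)
    sub_ids = [c.subject_id for c in covars]
    groups = [c.group for c in covars]

    def _load_schedule():
        return EventSchedule.from_tsv(cohort / "schedule.tsv")

    schedule = _stage("schedule", _load_schedule, manifest)

    def _load_ratings():
        path = cohort / "ratings.tsv"
        if not path.exists():
            raise FatigueMapError(f"ratings file not found: {path}")
        series = ratings_from_tsv(path)
        by_sub: dict[str, dict] = {}
        for s in series:
            by_sub.setdefault(s.subject_id, {})[s.scale] = s
        return by_sub

    ratings = _stage("design", _load_ratings, manifest)

    subject_maps: list[StatMap] = []
    for sub in sub_ids:
        def _subject():
            data, vox, affine = fio.read_volume(cohort / sub / "bold.nii.gz")
            mdat, _, _ = fio.read_volume(cohort / sub / "mask.nii.gz")
            n_keep = config.n_volumes_per_run - config.n_discard
            n_runs = data.shape[3] // n_keep
            bold = BoldDataset(
                data=data, tr_s=config.tr_s, brain_mask=mdat > 0,
                run_boundaries=tuple(r * n_keep for r in range(n_runs)),
                n_discarded_initial=config.n_discard,
                voxel_size_mm=vox, affine=affine,
            )
            bold = detrend_timeseries(bold)
            if config.smoothing_fwhm_mm:
                for v in range(bold.n_volumes):
                    bold.data[..., v] = _smooth_map(
                        bold.data[..., v], bold.brain_mask,
                        config.smoothing_fwhm_mm, bold.voxel_size_mm,
                    )
            amps = {
                s: interpolate_amplitudes(schedule, ratings[sub][s])
                for s in RATING_SCALES
            }
            design = build_design_matrix(
                schedule, amps, hrf=hrf, tr_s=config.tr_s,
                n_volumes_per_run=config.n_volumes_per_run,
                n_discard=config.n_discard, detrend=config.detrend,
                center_amplitudes=config.center_amplitudes,
            )
            result = fit_glm(bold, design)
            beta = result.betas["amr_fatigue"]
            if config.map_smoothing_fwhm_mm:
                # smooth subject-level maps so the group map's noise
                # smoothness matches the cluster calibration FWHM
                beta.values = _smooth_map(
                    beta.values, bold.brain_mask,
                    config.map_smoothing_fwhm_mm, bold.voxel_size_mm,
                )
            fio.write_volume(beta.values, out / f"{sub}_fatigue_beta.nii.gz",
                             voxel_size_mm=bold.voxel_size_mm, affine=bold.affine)
            return beta
        subject_maps.append(_stage(f"glm:{sub}", _subject, manifest))

    def _group():
        cov = None
        if config.use_covariates:
            cov = np.column_stack(
                [[c.age_years for c in covars], [c.education_years for c in covars]]
            )
        return group_difference_map(subject_maps, groups, covariates=cov,
                                    groups=("MS", "HC"))

    gmap = _stage("group", _group, manifest)
    fio.write_volume(gmap.values, out / "group_t.nii.gz",
                     voxel_size_mm=gmap.voxel_size_mm, affine=gmap.affine)

    mask = np.all(np.stack([np.isfinite(m.values) for m in subject_maps]), axis=0)
    roi = None
    if config.roi_path:
        rdat, _, _ = fio.read_volume(config.roi_path)
        roi = rdat > 0

    def _calibrate():
        cal_mask = mask & roi if roi is not None else mask
        return simulate_cluster_null(
            grid_shape=gmap.shape, voxel_size_mm=gmap.voxel_size_mm,
            mask=cal_mask, fwhm_mm=config.cluster_fwhm_mm,
            voxel_p=config.voxel_p, two_sided=config.two_sided,
            n_iterations=config.cluster_iterations,
            connectivity=config.connectivity, alpha=config.alpha,
            seed=config.seed,
        )

    calibration = _stage("calibrate", _calibrate, manifest)
    calibration.to_json(out / "calibration.json")
    logger.info("cluster extent threshold k_alpha=%d", calibration.k_alpha)

    def _threshold():
        target = restrict_to_roi(gmap, roi) if roi is not None else gmap
        return apply_cluster_threshold(
            target, voxel_p=config.voxel_p, k=calibration.k_alpha,
            connectivity=config.connectivity, two_sided=config.two_sided,
        )

    thresholded, table = _stage("threshold", _threshold, manifest)
    table = _add_world_coordinates(table, gmap.affine)
    fio.write_volume(thresholded.values, out / "group_t_thresholded.nii.gz",
                     voxel_size_mm=gmap.voxel_size_mm, affine=gmap.affine)
    table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    manifest["k_alpha"] = calibration.k_alpha
    manifest["n_clusters"] = int(len(table))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return ExperimentResult(
        group_map=gmap, thresholded=thresholded, clusters=table,
        k_alpha=calibration.k_alpha, manifest=manifest,
    )


def run_experiment2(config: PipelineConfig) -> ExperimentResult:
    """Trait-fatigue workflow: tensor fit, FA, lesion exclusion, regression."""
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"experiment": 2, "config": vars(config).copy()}
    logger.info("experiment 2 config: %s", manifest["config"])

    covars = _stage("covariates", lambda: read_covariates_tsv(cohort / "covars.tsv"),
                    manifest)

    fa_maps: list[FAMap] = []
    lesion_masks = []
    brain = None
    for cov in covars:
        sub = cov.subject_id

        def _subject():
            from .dti import DiffusionDataset

            data, vox, affine = fio.read_volume(cohort / sub / "dwi.nii.gz")
            mdat, _, _ = fio.read_volume(cohort / sub / "mask.nii.gz")
            bvals, bvecs = fio.read_bvals_bvecs(cohort / sub / "bvals",
                                                cohort / sub / "bvecs")
            ds = DiffusionDataset(
                dwi=data, bvals=bvals, bvecs=bvecs, brain_mask=mdat > 0,
                voxel_size_mm=vox, affine=affine,
            )
            tensors = fit_tensor(ds, weighted=config.weighted_tensor_fit)
            fa = compute_fa(tensors)
            fio.write_volume(fa.values, out / f"{sub}_fa.nii.gz",
                             voxel_size_mm=vox, affine=affine)
            lpath = cohort / sub / "lesions.nii.gz"
            lesion = fio.read_volume(lpath)[0] > 0 if lpath.exists() else None
            return fa, ds.brain_mask, lesion

        fa, bmask, lesion = _stage(f"tensor:{sub}", _subject, manifest)
        fa_maps.append(fa)
        brain = bmask if brain is None else (brain & bmask)
        if lesion is not None:
            lesion_masks.append(lesion)

    def _exclude():
        domain, removed = exclude_lesions(brain, lesion_masks)
        logger.info("lesion exclusion removed %d voxels", removed)
        manifest["lesion_voxels_removed"] = removed
        return domain

    domain = _stage("lesion_exclusion", _exclude, manifest)

    def _regress():
        return fa_fatigue_regression(
            fa_maps, covars, group=config.dti_group, analysis_mask=domain,
            fss_attribute=config.fss_attribute,
        )

    t_map, r2_map = _stage("regression", _regress, manifest)
    fio.write_volume(t_map.values, out / "fss_t.nii.gz",
                     voxel_size_mm=t_map.voxel_size_mm, affine=t_map.affine)
    fio.write_volume(r2_map.values, out / "fss_r2.nii.gz",
                     voxel_size_mm=r2_map.voxel_size_mm, affine=r2_map.affine)

    def _calibrate():
        return simulate_cluster_null(
            grid_shape=t_map.shape, voxel_size_mm=t_map.voxel_size_mm,
            mask=t_map.valid, fwhm_mm=config.cluster_fwhm_mm,
            voxel_p=config.voxel_p, two_sided=config.two_sided,
            n_iterations=config.cluster_iterations,
            connectivity=config.connectivity, alpha=config.alpha,
            seed=config.seed,
        )

    calibration = _stage("calibrate", _calibrate, manifest)
    calibration.to_json(out / "calibration.json")

    def _threshold():
        return apply_cluster_threshold(
            t_map, voxel_p=config.voxel_p, k=calibration.k_alpha,
            connectivity=config.connectivity, two_sided=config.two_sided,
        )

    thresholded, table = _stage("threshold", _threshold, manifest)
    table = _add_world_coordinates(table, t_map.affine)
    if len(table):
        # attach the model R^2 at each cluster peak
        peaks = table[["peak_x", "peak_y", "peak_z"]].to_numpy()
        table = table.assign(
            peak_r2=[float(r2_map.values[tuple(p)]) for p in peaks]
        )
    fio.write_volume(thresholded.values, out / "fss_t_thresholded.nii.gz",
                     voxel_size_mm=t_map.voxel_size_mm, affine=t_map.affine)
    table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    manifest["k_alpha"] = calibration.k_alpha
    manifest["n_clusters"] = int(len(table))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return ExperimentResult(
        group_map=t_map, thresholded=thresholded, clusters=table,
        k_alpha=calibration.k_alpha, manifest=manifest,
    )


def _add_world_coordinates(table: pd.DataFrame, affine: np.ndarray) -> pd.DataFrame:
    """Append world-space (mm) peak coordinates from the affine."""
    if not len(table):
        return table
    vox = np.column_stack(
        [table["peak_x"], table["peak_y"], table["peak_z"], np.ones(len(table))]
    )
    world = (affine @ vox.T).T[:, :3]
    return table.assign(
        peak_x_mm=world[:, 0], peak_y_mm=world[:, 1], peak_z_mm=world[:, 2]
    )
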