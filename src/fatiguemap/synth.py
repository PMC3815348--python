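"""Synthetic cohorts with known ground truth.

Every input the two analysis arms need is generated here: run-boundary rating
trajectories, fatigue-coupled BOLD time series for an MS and a control group,
and diffusion-weighted volumes produced from ground-truth tensor fields whose
tract FA is coupled to each subject's trait-fatigue score.  The generators
are forward models of the very effects the pipeline estimates, so recovery
can be scored against serialized truth.

Study conditions emulated by the defaults: a six-run event-related session of
32 eight-second trials per run (TR 2 s, 135 volumes per run with the first 5
discarded), 12 MS and 11 control subjects for the BOLD arm, 13 MS and 12
controls for the DWI arm (12 gradient directions at b = 1000 s/mm^2 plus
seven b = 0 volumes), MS rating trajectories starting higher than controls,
and a negative FA-FSS coupling restricted to one anisotropic tract region in
the MS group.  The synthetic grid is 24 x 24 x 16 at 3 mm isotropic; noise is
Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ValidationError
from .paradigm import (
    RATING_SCALES,
    EventSchedule,
    RatingSeries,
    build_rating_series,
    generate_schedule,
    interpolate_amplitudes,
    ratings_to_tsv,
)
from .glm import BoldDataset, DesignMatrix, HRFParams, build_design_matrix
from .dti import (
    DiffusionDataset,
    SubjectCovariates,
    components_to_matrices,
    prolate_eigenvalues,
    write_covariates_tsv,
)

DEFAULT_GRID = (24, 24, 16)
DEFAULT_VOXEL_MM = (3.0, 3.0, 3.0)

#: per-group rating trajectory ranges (VAS units): start at boundary 0 and
#: increment per boundary; MS reports more fatigue than controls
RATING_RANGES = {
    "MS": {"start": (30.0, 60.0), "slope": (1.0, 6.0)},
    "HC": {"start": (5.0, 25.0), "slope": (0.0, 3.0)},
}
#: the five non-fatigue scales drift around a low-to-middling baseline
NUISANCE_RATING_RANGES = {"start": (5.0, 35.0), "slope": (-2.0, 2.0)}


def ellipsoid_mask(shape, semiaxes_fraction=0.9) -> np.ndarray:
    """Brain stand-in: an axis-aligned ellipsoid inscribed in the grid."""
    grids = np.indices(shape).astype(float)
    center = [(s - 1) / 2 for s in shape]
    semi = [f * s / 2 for s, f in zip(shape, [semiaxes_fraction] * 3)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def sphere_mask(shape, center, radius_vox) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius_vox**2


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for the BOLD (state-fatigue) synthetic cohort."""

    n_ms: int = 12
    n_hc: int = 11
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_MM
    tr_s: float = 2.0
    n_runs: int = 6
    trials_per_run: int = 32
    n_volumes_per_run: int = 135
    n_discard: int = 5
    effect_center: tuple[float, float, float] = (14.0, 10.0, 8.0)
    effect_radius_vox: float = 2.5
    ms_effect: float = 10.0  # BOLD units per unit fatigue amplitude
    hc_effect: float = 0.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    drift_sd: float = 0.5  # per-run linear drift amplitude sd
    unit_response: float = 0.5  # trial-invariant response everywhere in brain
    nuisance_coupling_sd: float = 0.1
    rating_jitter_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ms < 2 or self.n_hc < 2:
            raise ValidationError("need at least 2 subjects per group")

    def brain_mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid_shape)

    def effect_region(self) -> np.ndarray:
        region = sphere_mask(self.grid_shape, self.effect_center, self.effect_radius_vox)
        region &= self.brain_mask()
        if not region.any():
            raise ConfigurationError("effect region lies outside the brain mask")
        return region


@dataclass(frozen=True)
class DwiCohortSpec:
    """Conditions for the DWI (trait-fatigue) synthetic cohort."""

    n_ms: int = 13
    n_hc: int = 12
    grid_shape: tuple[int, int, int] = (16, 16, 10)
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_MM
    b_value: float = 1000.0  # s/mm^2
    n_directions: int = 12
    n_b0: int = 7
    tract_center: tuple[float, float, float] = (8.0, 8.0, 5.0)
    tract_radius_vox: float = 2.5
    background_md: float = 0.7e-3  # mm^2/s
    tract_base_fa: float = 0.6
    fa_fss_slope_ms: float = -0.004  # FA units per FSS point (MS group)
    fa_fss_slope_hc: float = 0.0
    s0: float = 100.0
    noise_sd: float = 1.0
    lesion_fraction: float = 0.01  # MS white-matter lesion voxels outside tract
    fss_item_center: dict = field(
        default_factory=lambda: {"MS": 5.8, "HC": 2.0}
    )
    fss_item_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ms < 2 or self.n_hc < 2:
            raise ValidationError("need at least 2 subjects per group")

    def brain_mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid_shape)

    def tract_region(self) -> np.ndarray:
        region = sphere_mask(self.grid_shape, self.tract_center, self.tract_radius_vox)
        return region & self.brain_mask()


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n well-spread unit vectors on the upper hemisphere (deterministic)."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1): upper hemisphere
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def simulate_ratings(
    start_range: tuple[float, float],
    slope_range: tuple[float, float],
    jitter_sd: float = 3.0,
    subject_id: str = "sub-01",
    scale: str = "fatigue",
    n_boundaries: int = 7,
    seed: int | np.random.Generator = 0,
) -> RatingSeries:
    """Monotone-ish rating trajectory: start + slope*t + jitter, clipped to [0, 100]."""
    for name, (lo, hi) in (("start", start_range), ("slope", slope_range)):
        if lo > hi:
            raise ConfigurationError(f"{name}_range must be ordered, got ({lo}, {hi})")
    if not 0 <= start_range[0] <= start_range[1] <= 100:
        raise ConfigurationError("start_range must lie within [0, 100]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    start = rng.uniform(*start_range)
    slope = rng.uniform(*slope_range)
    t = np.arange(n_boundaries)
    vals = start + slope * t + (rng.normal(0, jitter_sd, n_boundaries) if jitter_sd else 0.0)
    vals = np.clip(vals, 0.0, 100.0)
    return build_rating_series(vals, subject_id=subject_id, scale=scale,
                               n_boundaries=n_boundaries)


def subject_rating_set(
    spec: CohortSpec, group: str, subject_id: str, rng: np.random.Generator
) -> dict[str, RatingSeries]:
    """All six scales for one subject; fatigue uses the group's ranges."""
    out = {}
    n_boundaries = spec.n_runs + 1
    fr = RATING_RANGES[group]
    out["fatigue"] = simulate_ratings(
        fr["start"], fr["slope"], spec.rating_jitter_sd, subject_id, "fatigue",
        n_boundaries=n_boundaries, seed=rng,
    )
    for scale in RATING_SCALES:
        if scale == "fatigue":
            continue
        nr = NUISANCE_RATING_RANGES
        out[scale] = simulate_ratings(
            nr["start"], nr["slope"], spec.rating_jitter_sd, subject_id, scale,
            n_boundaries=n_boundaries, seed=rng,
        )
    return out


def simulate_bold(
    spec: CohortSpec,
    schedule: EventSchedule,
    ratings: dict[str, RatingSeries],
    group: str = "MS",
    hrf: HRFParams = HRFParams(),
    seed: int | np.random.Generator = 0,
) -> tuple[BoldDataset, np.ndarray, DesignMatrix]:
    """Forward-model one subject's BOLD from the design.

    Voxel series = baseline + unit_response*unit column
    + effect(voxel)*fatigue AMR + per-voxel nuisance couplings to the other
    AMRs + per-run linear drift + Gaussian noise; effect(voxel) is the group
    effect inside the effect region and 0 elsewhere.  Returns the dataset,
    the ground-truth effect map, and the design used for generation.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    amplitudes = {
        s: interpolate_amplitudes(schedule, ratings[s]) for s in RATING_SCALES
    }
    design = build_design_matrix(
        schedule, amplitudes, hrf=hrf, tr_s=spec.tr_s,
        n_volumes_per_run=spec.n_volumes_per_run, n_discard=spec.n_discard,
    )
    mask = spec.brain_mask()
    region = spec.effect_region()
    effect = spec.ms_effect if group == "MS" else spec.hc_effect
    truth = np.where(region, effect, 0.0)

    n_vox = int(mask.sum())
    n_vol = design.n_volumes
    series = np.full((n_vox, n_vol), spec.baseline)
    series += spec.unit_response * design.column("unit")
    series += truth[mask][:, None] * design.column("amr_fatigue")
    for s in RATING_SCALES:
        if s == "fatigue":
            continue
        coupling = rng.normal(0.0, spec.nuisance_coupling_sd, n_vox)
        series += coupling[:, None] * design.column(f"amr_{s}")
    n_keep = spec.n_volumes_per_run - spec.n_discard
    for start in design.run_boundaries:
        slope = rng.normal(0.0, spec.drift_sd, n_vox)
        ramp = np.linspace(-1, 1, n_keep)
        series[:, start : start + n_keep] += slope[:, None] * ramp
    if spec.noise_sd:
        series += rng.normal(0.0, spec.noise_sd, series.shape)

    data = np.zeros(spec.grid_shape + (n_vol,))
    data[mask] = series
    bold = BoldDataset(
        data=data,
        tr_s=spec.tr_s,
        brain_mask=mask,
        run_boundaries=design.run_boundaries,
        n_discarded_initial=spec.n_discard,
        voxel_size_mm=spec.voxel_size_mm,
    )
    return bold, truth, design


def simulate_dwi(
    spec: DwiCohortSpec,
    fss_total: float,
    group: str = "MS",
    fss_reference: float | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[DiffusionDataset, np.ndarray]:
    """Forward-model one subject's DWI from a ground-truth tensor field.

    Background voxels are isotropic at ``background_md``; tract voxels carry
    a prolate tensor (principal axis x) whose FA is
    ``tract_base_fa + slope*(fss - reference)`` clipped to [0.05, 0.95].
    Signals follow S0*exp(-b g'Dg) plus Gaussian noise.  Returns the dataset
    and the ground-truth FA map.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mask = spec.brain_mask()
    tract = spec.tract_region()
    slope = spec.fa_fss_slope_ms if group == "MS" else spec.fa_fss_slope_hc
    if fss_reference is None:
        fss_reference = 9 * spec.fss_item_center[group]
    fa_tract = float(np.clip(
        spec.tract_base_fa + slope * (fss_total - fss_reference), 0.05, 0.95
    ))

    comp = np.zeros(spec.grid_shape + (6,))
    comp[mask, 0] = comp[mask, 1] = comp[mask, 2] = spec.background_md
    l1, l2, l3 = prolate_eigenvalues(fa_tract, spec.background_md)
    comp[tract, 0] = l1
    comp[tract, 1] = l2
    comp[tract, 2] = l3

    truth_fa = np.zeros(spec.grid_shape)
    truth_fa[tract] = fa_tract

    bvecs = np.vstack(
        [np.zeros((spec.n_b0, 3)), fibonacci_hemisphere(spec.n_directions)]
    )
    bvals = np.concatenate(
        [np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)]
    )
    D = components_to_matrices(comp[mask])  # V x 3 x 3
    gDg = np.einsum("ni,vij,nj->vn", bvecs, D, bvecs)  # V x n
    signal = spec.s0 * np.exp(-bvals[None, :] * gDg)
    if spec.noise_sd:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)

    dwi = np.zeros(spec.grid_shape + (len(bvals),))
    dwi[mask] = signal
    ds = DiffusionDataset(
        dwi=dwi, bvals=bvals, bvecs=bvecs, brain_mask=mask,
        voxel_size_mm=spec.voxel_size_mm,
    )
    return ds, truth_fa


def _draw_covariates(
    group: str, subject_id: str, rng: np.random.Generator,
    fss_item_center: dict, fss_item_sd: float,
    age_mean_sd={"MS": (47.0, 8.0), "HC": (34.0, 10.0)},
    edu_mean_sd={"MS": (15.5, 2.0), "HC": (16.0, 2.0)},
    trait_offset_sd={"MS": 1.25, "HC": 0.75},
) -> SubjectCovariates:
    am, asd = age_mean_sd[group]
    em, esd = edu_mean_sd[group]
    # a subject-level trait offset correlates the nine items, giving group
    # FSS-total spreads near the reported ~11.5 (MS) / ~7 (HC)
    offset = rng.normal(0.0, trait_offset_sd[group])
    items = np.clip(
        np.rint(rng.normal(fss_item_center[group] + offset, fss_item_sd, 9)), 1, 7
    )
    return SubjectCovariates(
        subject_id=subject_id,
        group=group,
        age_years=float(np.clip(rng.normal(am, asd), 20, 75)),
        education_years=float(np.clip(rng.normal(em, esd), 8, 22)),
        fss_items=tuple(items),
    )


def make_cohort(
    spec: CohortSpec | DwiCohortSpec,
    out_dir,
    seed: int | None = None,
    schedule_seed: int = 1,
) -> dict:
    """Write a full synthetic cohort to disk and return its ground truth.

    A :class:`CohortSpec` yields the BOLD (state-fatigue) cohort — per
    subject ``bold.nii.gz`` and ``mask.nii.gz``, plus cohort-level
    ``schedule.tsv``, ``ratings.tsv``, ``covars.tsv``, ``roi.nii.gz`` and
    ``truth.json``.  A :class:`DwiCohortSpec` yields the DWI (trait-fatigue)
    cohort — per subject ``dwi.nii.gz``, ``bvals``, ``bvecs``,
    ``mask.nii.gz``, ``lesions.nii.gz``, plus ``covars.tsv`` and
    ``truth.json``.  Deterministic given the spec seed (or ``seed``).
    """
    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    groups = ["MS"] * spec.n_ms + ["HC"] * spec.n_hc
    subjects = [f"sub-{i:02d}" for i in range(1, len(groups) + 1)]
    truth: dict = {"seed": int(seed), "subjects": {}, "spec": _spec_dict(spec)}
    covars = []

    if isinstance(spec, CohortSpec):
        schedule = generate_schedule(
            n_runs=spec.n_runs, trials_per_run=spec.trials_per_run,
            seed=schedule_seed,
        )
        schedule.to_tsv(out / "schedule.tsv")
        mask = spec.brain_mask()
        region = spec.effect_region()
        fio.write_volume(region.astype(np.int8), out / "roi.nii.gz",
                         voxel_size_mm=spec.voxel_size_mm)
        all_ratings = []
        truth["effect_region_voxels"] = np.argwhere(region).tolist()
        truth["ms_effect"] = spec.ms_effect
        truth["hc_effect"] = spec.hc_effect
        for sub, group in zip(subjects, groups):
            sdir = out / sub
            sdir.mkdir(exist_ok=True)
            ratings = subject_rating_set(spec, group, sub, rng)
            all_ratings.extend(ratings.values())
            bold, tmap, _ = simulate_bold(spec, schedule, ratings, group, seed=rng)
            fio.write_volume(bold.data.astype(np.float32), sdir / "bold.nii.gz",
                             voxel_size_mm=spec.voxel_size_mm)
            fio.write_volume(mask.astype(np.int8), sdir / "mask.nii.gz",
                             voxel_size_mm=spec.voxel_size_mm)
            covars.append(_draw_covariates(group, sub, rng,
                                           {"MS": 5.8, "HC": 2.0}, 1.0))
            truth["subjects"][sub] = {"group": group,
                                      "effect": spec.ms_effect if group == "MS"
                                      else spec.hc_effect}
        ratings_to_tsv(all_ratings, out / "ratings.tsv")
    elif isinstance(spec, DwiCohortSpec):
        mask = spec.brain_mask()
        tract = spec.tract_region()
        truth["tract_voxels"] = np.argwhere(tract).tolist()
        truth["fa_fss_slope_ms"] = spec.fa_fss_slope_ms
        truth["fa_fss_slope_hc"] = spec.fa_fss_slope_hc
        for sub, group in zip(subjects, groups):
            sdir = out / sub
            sdir.mkdir(exist_ok=True)
            cov = _draw_covariates(group, sub, rng, spec.fss_item_center,
                                   spec.fss_item_sd)
            covars.append(cov)
            ds, truth_fa = simulate_dwi(spec, cov.fss_total, group, seed=rng)
            fio.write_volume(ds.dwi.astype(np.float32), sdir / "dwi.nii.gz",
                             voxel_size_mm=spec.voxel_size_mm)
            fio.write_volume(mask.astype(np.int8), sdir / "mask.nii.gz",
                             voxel_size_mm=spec.voxel_size_mm)
            fio.write_bvals_bvecs(ds.bvals, ds.bvecs,
                                  sdir / "bvals", sdir / "bvecs")
            lesions = np.zeros(spec.grid_shape, dtype=np.int8)
            if group == "MS" and spec.lesion_fraction > 0:
                candidates = np.argwhere(mask & ~tract)
                n_les = max(1, int(spec.lesion_fraction * len(candidates)))
                pick = rng.choice(len(candidates), size=n_les, replace=False)
                lesions[tuple(candidates[pick].T)] = 1
            fio.write_volume(lesions, sdir / "lesions.nii.gz",
                             voxel_size_mm=spec.voxel_size_mm)
            truth["subjects"][sub] = {
                "group": group, "fss_total": cov.fss_total,
                "ground_truth_tract_fa": float(truth_fa[tract].mean())
                if tract.any() else None,
            }
    else:
        raise ConfigurationError(f"unknown spec type {type(spec).__name__}")

    write_covariates_tsv(covars, out / "covars.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
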