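"""Diffusion-tensor fitting, fractional anisotropy, and FA-fatigue regression.

Water diffusion in white matter is summarized per voxel by a symmetric 3x3
tensor D (mm^2/s).  For a diffusion weighting b (s/mm^2) along unit gradient
g the signal follows the Stejskal-Tanner relation

    S = S0 * exp(-b * g' D g)

so the six unique tensor components are recovered by ordinary least squares
on log-signal ratios (the classical log-linear fit).  Fractional anisotropy
condenses the sorted eigenvalues l1 >= l2 >= l3 into a 0-1 scalar

    FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2)

(0 for isotropic diffusion, 1 in the single-stick limit), a standard proxy
for white-matter integrity.  Trait fatigue is then related to FA voxelwise by
multiple linear regression of FA on the Fatigue Severity Scale total with age
and education as covariates, within one diagnostic group, after removing
voxels covered by any subject's white-matter lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError
from .glm import StatMap, degenerate_variance, ols_fit, _check_full_rank

#: clamp floor for non-positive diffusion signals, as a fraction of S0
SIGNAL_FLOOR_FRACTION = 1e-6


@dataclass
class DiffusionDataset:
    """Multi-direction DWI with b-values, gradients and brain mask."""

    dwi: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray  # n_volumes x 3, unit norm for b > 0
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.dwi = np.asarray(self.dwi, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.dwi.ndim != 4:
            raise ValidationError("DWI must be 4D (x, y, z, volume)")
        n = self.dwi.shape[3]
        if self.bvals.shape != (n,):
            raise ValidationError(f"expected {n} b-values, got {self.bvals.shape}")
        if self.bvecs.shape != (n, 3):
            raise ValidationError(f"expected {n}x3 bvecs, got {self.bvecs.shape}")
        if self.brain_mask.shape != self.dwi.shape[:3]:
            raise GridMismatchError("mask grid does not match DWI grid")
        if not np.any(self.bvals == 0):
            raise ValidationError("at least one b=0 volume is required")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1) > 1e-3):
            raise ValidationError("gradient directions must be unit vectors for b > 0")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_directions(self) -> int:
        return int(np.sum(self.bvals > 0))


@dataclass
class TensorField:
    """Per-voxel symmetric tensor components and sorted eigenvalues.

    ``components`` stores (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) along the last axis;
    ``eigenvalues`` are sorted descending.  ``valid`` is False where the fit
    was degenerate (clamped signals, S0 = 0, negative eigenvalues clamped).
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    valid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])


@dataclass
class FAMap:
    """Per-voxel fractional anisotropy in [0, 1]."""

    values: np.ndarray
    valid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographics and trait fatigue for one subject.

    ``fss_items`` are the nine Fatigue Severity Scale responses (1-7 each);
    the summed total therefore lies in [9, 63] and the mean in [1, 7].  The
    total is the default regression covariate.
    """

    subject_id: str
    group: str  # MS | HC
    age_years: float
    education_years: float
    fss_items: tuple[float, ...] = field(default=(4.0,) * 9)

    def __post_init__(self):
        if self.group not in ("MS", "HC"):
            raise ValidationError(f"group must be MS or HC, got {self.group!r}")
        if len(self.fss_items) != 9 or any(not 1 <= x <= 7 for x in self.fss_items):
            raise ValidationError("FSS requires nine items, each in [1, 7]")
        if self.age_years <= 0 or self.education_years <= 0:
            raise ValidationError("age and education must be positive")

    @property
    def fss_total(self) -> float:
        return float(sum(self.fss_items))

    @property
    def fss_mean(self) -> float:
        return self.fss_total / 9.0


def design_from_gradients(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear tensor design rows  b*[gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz]."""
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)
    return b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def components_to_matrices(components: np.ndarray) -> np.ndarray:
    """(..., 6) component arrays -> (..., 3, 3) symmetric matrices."""
    c = np.asarray(components, dtype=float)
    out = np.zeros(c.shape[:-1] + (3, 3))
    out[..., 0, 0] = c[..., 0]
    out[..., 1, 1] = c[..., 1]
    out[..., 2, 2] = c[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
    return out


def fit_tensor(data: DiffusionDataset, weighted: bool = False) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    S0 is the mean of the b=0 volumes.  Non-positive signals are clamped to a
    small positive floor and the voxel flagged; so are voxels with S0 = 0 and
    voxels whose negative eigenvalues had to be clamped to zero.  With
    ``weighted`` the rows are weighted by the squared signal (WLS).
    """
    nz = data.bvals > 0
    if np.sum(nz) < 6:
        raise ValidationError("tensor fit requires >= 6 nonzero-b directions")
    B = design_from_gradients(data.bvals[nz], data.bvecs[nz])
    if np.linalg.matrix_rank(B) < 6:
        raise ValidationError(
            "gradient directions are not independent (rank-deficient tensor design); "
            "6 non-collinear directions are required"
        )
    mask = data.brain_mask
    shape = mask.shape
    s0 = data.dwi[..., ~nz].mean(axis=-1)[mask]  # V
    S = data.dwi[mask][:, nz]  # V x n

    valid = np.ones(s0.shape, dtype=bool)
    bad_s0 = s0 <= 0
    valid &= ~bad_s0
    s0_safe = np.where(bad_s0, 1.0, s0)
    floor = SIGNAL_FLOOR_FRACTION * s0_safe[:, None]
    clamped = S < floor
    valid &= ~clamped.any(axis=1)
    S = np.maximum(S, floor)
    Y = -np.log(S / s0_safe[:, None])  # V x n, equals b g'Dg + noise

    if weighted:
        # per-voxel WLS with weights S^2: solve voxel batches
        comp = np.empty((Y.shape[0], 6))
        W = S**2
        Bt = B.T
        for v in range(Y.shape[0]):
            Aw = Bt * W[v]  # 6 x n
            comp[v] = np.linalg.solve(Aw @ B, Aw @ Y[v])
    else:
        comp = np.linalg.lstsq(B, Y.T, rcond=None)[0].T  # V x 6

    mats = components_to_matrices(comp)
    evals = np.linalg.eigvalsh(mats)[:, ::-1]  # descending
    neg = evals < 0
    valid &= ~neg.any(axis=1)
    evals = np.clip(evals, 0, None)

    comp_vol = np.full(shape + (6,), np.nan)
    comp_vol[mask] = comp
    eval_vol = np.full(shape + (3,), np.nan)
    eval_vol[mask] = evals
    valid_vol = np.zeros(shape, dtype=bool)
    valid_vol[mask] = valid
    return TensorField(
        components=comp_vol,
        eigenvalues=eval_vol,
        valid=valid_vol,
        voxel_size_mm=data.voxel_size_mm,
        affine=data.affine,
    )


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Closed-form FA from (..., 3) eigenvalue arrays; 0 where all zero."""
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    fa = np.zeros(lam.shape[:-1])
    ok = den > 0
    fa[ok] = np.sqrt(1.5) * num[ok] / den[ok]
    return np.clip(fa, 0.0, 1.0)


def compute_fa(tensors: TensorField) -> FAMap:
    """Fractional anisotropy map from a fitted tensor field.

    Voxels with zero mean diffusivity (all eigenvalues 0) get FA = 0 and are
    flagged invalid rather than NaN.
    """
    finite = np.all(np.isfinite(tensors.eigenvalues), axis=-1)
    evals = np.where(finite[..., None], tensors.eigenvalues, 0.0)
    fa = fa_from_eigenvalues(evals)
    zero_md = finite & (evals.sum(axis=-1) <= 0)
    valid = tensors.valid & finite & ~zero_md
    fa[~finite] = np.nan
    return FAMap(
        values=fa,
        valid=valid,
        voxel_size_mm=tensors.voxel_size_mm,
        affine=tensors.affine,
    )


def exclude_lesions(
    analysis_mask: np.ndarray, lesion_masks: list[np.ndarray]
) -> tuple[np.ndarray, int]:
    """Remove the union of subject lesion masks from the analysis domain.

    Returns the reduced mask and the number of removed voxels (the union of
    lesions intersected with the analysis mask).
    """
    mask = np.asarray(analysis_mask).astype(bool)
    union = np.zeros_like(mask)
    for lm in lesion_masks:
        lm = np.asarray(lm).astype(bool)
        if lm.shape != mask.shape:
            raise GridMismatchError(
                f"lesion mask grid {lm.shape} != analysis grid {mask.shape}"
            )
        union |= lm
    removed = int((mask & union).sum())
    out = mask & ~union
    if not out.any():
        raise ValidationError("lesion exclusion removed the entire analysis domain")
    return out, removed


def fa_fatigue_regression(
    fa_maps: list[FAMap],
    covariates: list[SubjectCovariates],
    group: str = "MS",
    analysis_mask: np.ndarray | None = None,
    fss_attribute: str = "fss_total",
) -> tuple[StatMap, StatMap]:
    """Voxelwise OLS of FA on [intercept, FSS, age, education] within a group.

    Returns the t map for the FSS coefficient (df = n - 4) and the model R^2
    map.  Raises when the selected group has < 5 subjects, when FSS has no
    variance, or when covariate columns are collinear (naming the pair).
    """
    if len(fa_maps) != len(covariates):
        raise ValidationError("one covariate record per FA map required")
    sel = [i for i, c in enumerate(covariates) if c.group == group]
    if len(sel) < 5:
        raise ValidationError(
            f"need >= 5 subjects in group {group!r}, got {len(sel)}"
        )
    maps = [fa_maps[i] for i in sel]
    covs = [covariates[i] for i in sel]
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise GridMismatchError(f"FA maps on different grids: {shapes}")

    fss = np.array([getattr(c, fss_attribute) for c in covs])
    age = np.array([c.age_years for c in covs])
    edu = np.array([c.education_years for c in covs])
    if np.ptp(fss) == 0:
        raise ValidationError("FSS scores are constant across subjects (no variance)")
    X = np.column_stack([np.ones(len(covs)), fss, age, edu])
    _check_full_rank(X, ["intercept", "fss", "age", "education"])

    data = np.stack([m.values for m in maps], axis=-1)
    valid = np.all(np.stack([m.valid for m in maps], axis=-1), axis=-1)
    if analysis_mask is not None:
        am = np.asarray(analysis_mask).astype(bool)
        if am.shape != valid.shape:
            raise GridMismatchError("analysis mask grid does not match FA grid")
        valid &= am
    Y = data[valid].T  # n x V
    beta, sigma2, xtx_inv, df = ols_fit(X, Y)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    tvals = np.zeros(se.shape)
    ok = (se > 0) & ~degenerate_variance(sigma2, Y)
    tvals[ok] = beta[1][ok] / se[ok]
    ybar = Y.mean(axis=0)
    tss = np.einsum("nv,nv->v", Y - ybar, Y - ybar)
    rss = sigma2 * df
    r2 = np.zeros(tss.shape)
    pos = tss > 0
    r2[pos] = 1 - rss[pos] / tss[pos]
    r2 = np.clip(r2, 0.0, 1.0)

    ref = maps[0]
    t_vol = np.full(valid.shape, np.nan)
    t_vol[valid] = tvals
    r2_vol = np.full(valid.shape, np.nan)
    r2_vol[valid] = r2
    ok_vol = np.zeros(valid.shape, dtype=bool)
    ok_vol[valid] = ok
    t_map = StatMap(
        values=t_vol, stat_kind="t", df=df,
        voxel_size_mm=ref.voxel_size_mm, affine=ref.affine, valid=ok_vol,
    )
    r2_map = StatMap(
        values=r2_vol, stat_kind="R2", df=df,
        voxel_size_mm=ref.voxel_size_mm, affine=ref.affine, valid=ok_vol,
    )
    return t_map, r2_map


def prolate_eigenvalues(fa: float, md: float) -> tuple[float, float, float]:
    """Eigenvalues of a prolate (cigar) tensor with given FA and mean diffusivity.

    With l1 = md*(1+2d), l2 = l3 = md*(1-d) the closed form gives
    FA = sqrt(3)*d / sqrt(1+2d^2), inverted as d = FA / sqrt(3 - 2 FA^2).
    Valid for FA in [0, ~0.97] where l2 stays positive.
    """
    if not 0 <= fa < 1:
        raise ValidationError(f"FA must lie in [0, 1), got {fa}")
    d = fa / np.sqrt(3.0 - 2.0 * fa**2)
    l1 = md * (1 + 2 * d)
    l23 = md * (1 - d)
    if l23 < 0:
        raise ValidationError(f"FA {fa} not realizable with a prolate tensor")
    return float(l1), float(l23), float(l23)


def read_covariates_tsv(path) -> list[SubjectCovariates]:
    """Read subject covariates from a table with columns subject, group,
    age_years, education_years, fss_item1..fss_item9."""
    df = pd.read_csv(path, sep="\t")
    out = []
    item_cols = [f"fss_item{i}" for i in range(1, 10)]
    for _, row in df.iterrows():
        out.append(
            SubjectCovariates(
                subject_id=str(row["subject"]),
                group=str(row["group"]),
                age_years=float(row["age_years"]),
                education_years=float(row["education_years"]),
                fss_items=tuple(float(row[c]) for c in item_cols),
            )
        )
    return out


def write_covariates_tsv(covariates: list[SubjectCovariates], path) -> None:
    rows = []
    for c in covariates:
        row = {
            "subject": c.subject_id,
            "group": c.group,
            "age_years": c.age_years,
            "education_years": c.education_years,
        }
        row.update({f"fss_item{i+1}": v for i, v in enumerate(c.fss_items)})
        row["fss_total"] = c.fss_total
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
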