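"""Hemodynamic modeling and voxelwise general linear models.

The BOLD response to each trial is modeled as a delayed Gamma kernel

    h(t) = (t / (p*q))**p * exp(p - t/q),   t >= 0

with shape ``p`` (dimensionless) and time scale ``q`` (seconds), normalized to
unit peak; the peak sits at ``t = p*q`` (~4.7 s for the defaults p=8.6,
q=0.547).  Each trial contributes seven regressors: one unit-amplitude kernel
shared by all trials (trial-invariant response) and six amplitude-modulated
regressors (AMRs) whose per-event heights are the interpolated subjective
ratings, one per rating scale.  Regressors are built by convolving per-run
impulse trains with the kernel on a fine grid and sampling at the retained
volume acquisition times.

Voxelwise fitting is ordinary least squares; t contrasts use the classical
c'b / sqrt(s2 * c'(X'X)^-1 c) form with df = n - rank(X).  Group comparison
of per-subject beta maps is a per-voxel two-sample t-test, optionally
adjusting for subject-level covariates by including them in the voxelwise
regression (df = n1 + n2 - 2 - n_covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GridMismatchError, ValidationError
from .paradigm import RATING_SCALES, AmplitudeSeries, EventSchedule

#: fill value for voxels outside the analysis mask
MISSING = np.nan

#: acquisition defaults (seconds / counts)
DEFAULT_TR_S = 2.0
DEFAULT_VOLUMES_PER_RUN = 135
DEFAULT_N_DISCARD = 5


# --------------------------------------------------------------------------
# hemodynamic response
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Delayed-Gamma kernel parameters.

    ``shape * scale_s`` is the time-to-peak in seconds.  ``duration_s`` is the
    length of kernel support to sample and must cover the peak; ``dt_s`` is
    the sampling step used when building regressors.
    """

    shape: float = 8.6
    scale_s: float = 0.547
    duration_s: float = 20.0
    dt_s: float = 0.1

    def __post_init__(self):
        if self.shape <= 0 or self.scale_s <= 0 or self.dt_s <= 0:
            raise ConfigurationError("HRF shape, scale_s and dt_s must be positive")
        if self.duration_s < self.shape * self.scale_s:
            raise ConfigurationError(
                "HRF duration_s must cover the peak at shape*scale_s "
                f"= {self.shape * self.scale_s:g} s"
            )

    @property
    def peak_time_s(self) -> float:
        return self.shape * self.scale_s


def gamma_hrf(params: HRFParams = HRFParams()):
    """Sample the delayed-Gamma kernel on its time grid.

    Returns ``(t, h)`` with ``h(0) = 0``, ``h >= 0`` and unit peak.
    """
    t = np.arange(0.0, params.duration_s + params.dt_s / 2, params.dt_s)
    h = _gamma_kernel(t, params.shape, params.scale_s)
    return t, h / h.max()


def _gamma_kernel(t, p, q):
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    # log-space evaluation avoids overflow for large p
    h[pos] = np.exp(p * np.log(tp / (p * q)) + p - tp / q)
    return h


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """Volumes x regressors design with metadata.

    Rows correspond to retained volumes (after per-run discards), in run
    order; ``run_boundaries[r]`` is the first row index of run ``r``.
    """

    values: np.ndarray
    column_labels: tuple[str, ...]
    tr_s: float
    run_boundaries: tuple[int, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.column_labels):
            raise ValidationError("design values must be 2D with one label per column")
        if not np.all(np.isfinite(v)):
            raise ValidationError("design matrix contains non-finite entries")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.column_labels.index(label)]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=list(self.column_labels)).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class BoldDataset:
    """A 4D BOLD time series with mask and run structure."""

    data: np.ndarray
    tr_s: float
    brain_mask: np.ndarray
    run_boundaries: tuple[int, ...]
    n_discarded_initial: int = 0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.data.ndim != 4:
            raise ValidationError("BOLD data must be 4D (x, y, z, volume)")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise GridMismatchError(
                f"mask grid {self.brain_mask.shape} does not match "
                f"BOLD grid {self.data.shape[:3]}"
            )
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def run_slices(self) -> list[slice]:
        starts = list(self.run_boundaries)
        stops = starts[1:] + [self.n_volumes]
        return [slice(a, b) for a, b in zip(starts, stops)]


@dataclass
class StatMap:
    """A 3D statistic map with degrees of freedom and grid metadata.

    ``valid`` flags voxels with a defined statistic; out-of-mask voxels hold
    NaN, degenerate in-mask voxels (e.g. zero residual variance) hold 0 with
    ``valid`` False so NaN never propagates from them.
    """

    values: np.ndarray
    stat_kind: str  # beta | t | R2
    df: int | None = None
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("StatMap values must be 3D")
        if self.stat_kind == "t" and (self.df is None or self.df <= 0):
            raise ValidationError("t maps require df > 0")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid).astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def build_design_matrix(
    schedule: EventSchedule,
    amplitudes: dict[str, AmplitudeSeries],
    hrf: HRFParams = HRFParams(),
    tr_s: float = DEFAULT_TR_S,
    n_volumes_per_run: int = DEFAULT_VOLUMES_PER_RUN,
    n_discard: int = DEFAULT_N_DISCARD,
    detrend: bool = False,
    center_amplitudes: bool = False,
) -> DesignMatrix:
    """Assemble the unit + six-AMR design matrix.

    Column ``unit`` is the convolution of a unit-height impulse train (one
    impulse per trial onset) with the HRF; each AMR column uses the per-event
    amplitudes of its scale as impulse heights.  Convolution runs per run on
    a grid of step ``hrf.dt_s`` (<= 0.1 s) and is sampled at the acquisition
    times of the retained volumes (the first retained volume of each run
    defines t = 0 for that run's trials).  ``detrend`` appends per-run
    intercept and linear-trend columns; ``center_amplitudes`` subtracts each
    AMR's per-run mean impulse height before convolution.
    """
    if tr_s <= 0:
        raise ConfigurationError("tr_s must be positive")
    if hrf.dt_s > 0.1 + 1e-12:
        raise ConfigurationError("hrf.dt_s must be <= 0.1 s for regressor building")
    missing = [s for s in RATING_SCALES if s not in amplitudes]
    if missing:
        raise ValidationError(f"amplitudes missing for scales: {missing}")
    for scale, amp in amplitudes.items():
        if len(amp) != schedule.n_trials:
            raise ValidationError(
                f"amplitude series for {scale!r} has {len(amp)} events "
                f"but schedule has {schedule.n_trials}"
            )

    n_keep = n_volumes_per_run - n_discard
    if n_keep < 1:
        raise ConfigurationError("n_discard leaves no volumes")
    _, h = gamma_hrf(hrf)
    vol_times = np.arange(n_keep) * tr_s
    last_onset = float(schedule.events["onset_s"].max())
    n_grid = int(np.ceil(
        (max(vol_times[-1], last_onset) + hrf.duration_s) / hrf.dt_s
    )) + 1

    labels = ["unit"] + [f"amr_{s}" for s in RATING_SCALES]
    cols = {lab: [] for lab in labels}
    run_boundaries = []
    row = 0
    for run in range(1, schedule.n_runs + 1):
        run_boundaries.append(row)
        ev = schedule.run_events(run)
        onset_idx = np.rint(ev["onset_s"].to_numpy() / hrf.dt_s).astype(int)
        vol_idx = np.rint(vol_times / hrf.dt_s).astype(int)

        def _convolved(heights):
            train = np.zeros(n_grid)
            np.add.at(train, onset_idx, heights)
            return np.convolve(train, h)[:n_grid][vol_idx]

        cols["unit"].append(_convolved(np.ones(len(ev))))
        for scale in RATING_SCALES:
            heights = amplitudes[scale].amplitudes[ev.index.to_numpy()]
            if center_amplitudes:
                heights = heights - heights.mean()
            cols[f"amr_{scale}"].append(_convolved(heights))
        row += n_keep

    values = np.column_stack([np.concatenate(cols[lab]) for lab in labels])
    if detrend:
        drift_cols, drift_labels = [], []
        for r, start in enumerate(run_boundaries, start=1):
            const = np.zeros(values.shape[0])
            lin = np.zeros(values.shape[0])
            const[start : start + n_keep] = 1.0
            lin[start : start + n_keep] = np.linspace(-1, 1, n_keep)
            drift_cols += [const, lin]
            drift_labels += [f"drift_run{r}_const", f"drift_run{r}_lin"]
        values = np.column_stack([values] + drift_cols)
        labels = labels + drift_labels

    zero_task = [lab for lab in labels[:7] if not np.any(values[:, labels.index(lab)])]
    if "unit" in zero_task:
        raise ValidationError("unit regressor is identically zero")
    return DesignMatrix(
        values=values,
        column_labels=tuple(labels),
        tr_s=tr_s,
        run_boundaries=tuple(run_boundaries),
    )


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def detrend_timeseries(bold: BoldDataset) -> BoldDataset:
    """Remove the per-voxel, per-run least-squares line (mean included).

    The result is residualized: each run of each voxel has zero mean and no
    linear trend.
    """
    out = bold.data.copy()
    for sl in bold.run_slices():
        n = sl.stop - sl.start
        if n < 3:
            raise ValidationError("detrending requires >= 3 volumes per run")
        t = np.linspace(-1, 1, n)
        X = np.column_stack([np.ones(n), t])
        seg = out[..., sl].reshape(-1, n).T  # n x V
        beta = np.linalg.lstsq(X, seg, rcond=None)[0]
        out[..., sl] = (seg - X @ beta).T.reshape(bold.data.shape[:3] + (n,))
    return BoldDataset(
        data=out,
        tr_s=bold.tr_s,
        brain_mask=bold.brain_mask,
        run_boundaries=bold.run_boundaries,
        n_discarded_initial=bold.n_discarded_initial,
        voxel_size_mm=bold.voxel_size_mm,
        affine=bold.affine,
    )


def _check_full_rank(X: np.ndarray, labels) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify near-collinear column pairs for the error message
        Xn = X / np.maximum(np.linalg.norm(X, axis=0), 1e-300)
        corr = np.abs(Xn.T @ Xn)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear columns: {labels[i]!r} and {labels[j]!r}"
        )


def ols_fit(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of many responses on one design.

    ``X`` is n x p, ``Y`` is n x V.  Returns ``(beta, sigma2, xtx_inv, df)``
    with ``beta`` p x V, ``sigma2`` the residual variance RSS/(n - p) per
    response, and ``df = n - p`` (X must be full column rank).
    """
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    if df <= 0:
        raise ValidationError(f"no residual degrees of freedom (n={n}, p={p})")
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    return beta, sigma2, xtx_inv, df


def degenerate_variance(sigma2: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Voxels whose residual variance is at cancellation level (effectively 0).

    An exactly-modeled voxel leaves residuals of order eps*||y||, so its
    computed variance is ~eps^2 * scale rather than exactly zero; such voxels
    must be flagged instead of producing astronomically large t values.
    """
    scale = np.mean(Y**2, axis=0)
    return sigma2 <= 1e-24 * np.maximum(scale, np.finfo(float).tiny)


@dataclass
class GLMResult:
    """Voxelwise OLS fit: per-regressor betas plus residual variance."""

    betas: dict[str, StatMap]
    sigma2: StatMap
    design: DesignMatrix
    df: int
    mask: np.ndarray = field(repr=False)
    xtx_inv: np.ndarray = field(repr=False)
    degenerate: np.ndarray = field(repr=False, default=None)


def fit_glm(bold: BoldDataset, design: DesignMatrix) -> GLMResult:
    """Fit the design voxelwise by OLS inside the brain mask.

    Out-of-mask voxels are NaN in every returned map.
    """
    if design.n_volumes != bold.n_volumes:
        raise ValidationError(
            f"design has {design.n_volumes} rows but BOLD has "
            f"{bold.n_volumes} retained volumes"
        )
    X = design.values
    _check_full_rank(X, design.column_labels)
    mask = bold.brain_mask
    Y = bold.data[mask].T  # n x V
    beta, sigma2, xtx_inv, df = ols_fit(X, Y)
    deg = np.zeros(mask.shape, dtype=bool)
    deg[mask] = degenerate_variance(sigma2, Y)

    def _to_map(flat, kind, df_=None):
        vol = np.full(mask.shape, MISSING)
        vol[mask] = flat
        return StatMap(
            values=vol, stat_kind=kind, df=df_,
            voxel_size_mm=bold.voxel_size_mm, affine=bold.affine,
        )

    betas = {
        lab: _to_map(beta[i], "beta") for i, lab in enumerate(design.column_labels)
    }
    return GLMResult(
        betas=betas,
        sigma2=_to_map(sigma2, "sigma2"),
        design=design,
        df=df,
        mask=mask,
        xtx_inv=xtx_inv,
        degenerate=deg,
    )


def contrast_t(result: GLMResult, contrast) -> StatMap:
    """t map for a contrast of regression coefficients.

    Degenerate voxels (zero residual variance) get value 0 with
    ``valid=False`` instead of an infinite or NaN statistic.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(result.design.column_labels),):
        raise ValidationError(
            f"contrast length {c.size} != {len(result.design.column_labels)} regressors"
        )
    if not np.any(c):
        raise ValidationError("contrast vector is all zeros")
    mask = result.mask
    cb = np.zeros(mask.shape)
    for i, lab in enumerate(result.design.column_labels):
        if c[i]:
            cb[mask] = cb[mask] + c[i] * result.betas[lab].values[mask]
    s2 = result.sigma2.values[mask]
    var_scale = float(c @ result.xtx_inv @ c)
    se = np.sqrt(s2 * var_scale)
    tvals = np.zeros(se.shape)
    ok = (se > 0) & ~result.degenerate[mask]
    tvals[ok] = cb[mask][ok] / se[ok]
    vol = np.full(mask.shape, MISSING)
    vol[mask] = tvals
    valid = np.zeros(mask.shape, dtype=bool)
    valid[mask] = ok
    return StatMap(
        values=vol, stat_kind="t", df=result.df,
        voxel_size_mm=result.sigma2.voxel_size_mm, affine=result.sigma2.affine,
        valid=valid,
    )


# --------------------------------------------------------------------------
# group level
# --------------------------------------------------------------------------

def group_difference_map(
    subject_maps: list[StatMap],
    group_labels: list[str],
    covariates: np.ndarray | None = None,
    groups: tuple[str, str] = ("MS", "HC"),
) -> StatMap:
    """Per-voxel two-sample t map of subject-level maps (groups[0] - groups[1]).

    With ``covariates`` (n_subjects x n_cov), each voxel is regressed on
    [intercept, group indicator, covariates] and the group coefficient's t is
    returned with df = n - 2 - n_cov; without covariates this equals the
    pooled two-sample t-test.
    """
    if len(subject_maps) != len(group_labels):
        raise ValidationError("one group label per subject map required")
    shapes = {m.shape for m in subject_maps}
    if len(shapes) != 1:
        raise GridMismatchError(f"subject maps on different grids: {shapes}")
    labels = np.asarray(group_labels)
    n0, n1 = int(np.sum(labels == groups[0])), int(np.sum(labels == groups[1]))
    if n0 < 2 or n1 < 2:
        raise ValidationError(
            f"need >= 2 subjects per group, got {groups[0]}={n0}, {groups[1]}={n1}"
        )
    data = np.stack([m.values for m in subject_maps], axis=-1)  # x,y,z,n
    mask = np.all(np.isfinite(data), axis=-1)
    Y = data[mask].T  # n x V
    # centered indicator: coefficient = mean(groups[0]) - mean(groups[1])
    ind = np.where(labels == groups[0], 1.0, 0.0)
    X_cols = [np.ones(len(labels)), ind]
    col_names = ["intercept", "group"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(labels):
            cov = cov.T
        if cov.shape[0] != len(labels):
            raise ValidationError("covariates must have one row per subject")
        for k in range(cov.shape[1]):
            X_cols.append(cov[:, k] - cov[:, k].mean())
            col_names.append(f"cov{k}")
    X = np.column_stack(X_cols)
    _check_full_rank(X, col_names)
    beta, sigma2, xtx_inv, df = ols_fit(X, Y)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    tvals = np.zeros(se.shape)
    ok = (se > 0) & ~degenerate_variance(sigma2, Y)
    tvals[ok] = beta[1][ok] / se[ok]
    vol = np.full(mask.shape, MISSING)
    vol[mask] = tvals
    valid = np.zeros(mask.shape, dtype=bool)
    valid[mask] = ok
    ref = subject_maps[0]
    return StatMap(
        values=vol, stat_kind="t", df=df,
        voxel_size_mm=ref.voxel_size_mm, affine=ref.affine, valid=valid,
    )
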