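"""Monte-Carlo cluster-extent thresholding.

Voxelwise thresholding at an uncorrected probability ``voxel_p`` leaves many
false-positive voxels; cluster-extent correction keeps only contiguous
suprathreshold clusters of at least ``k`` voxels, with ``k`` calibrated by
simulating smooth Gaussian null fields so that the family-wise probability of
any surviving cluster is at most ``alpha`` (the AlphaSim approach).  The
calibration depends on the grid, the analysis mask, the assumed spatial
smoothness (mm FWHM — a required input, since it is a property of the data)
and the contiguity convention; calibration and application must use the same
settings.

Contiguity conventions: ``faces`` (6-neighborhood), ``faces+edges`` (18) and
``faces+edges+corners`` (26, the default).  Positive and negative
suprathreshold voxels are clustered separately under two-sided thresholding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConfigurationError, ValidationError
from .glm import StatMap

CONNECTIVITY = {
    "faces": 1,
    "faces+edges": 2,
    "faces+edges+corners": 3,
}


def _structure(connectivity: str) -> np.ndarray:
    try:
        rank = CONNECTIVITY[connectivity]
    except KeyError:
        raise ConfigurationError(
            f"connectivity must be one of {sorted(CONNECTIVITY)}, got {connectivity!r}"
        ) from None
    return ndimage.generate_binary_structure(3, rank)


def label_clusters(
    binary_map: np.ndarray,
    connectivity: str = "faces+edges+corners",
    values: np.ndarray | None = None,
    sign: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Connected-component labeling of a 3D binary map.

    Returns ``(labels, table)``: ``labels`` assigns cluster ids 1..n in
    lexicographic order of each cluster's first voxel; ``table`` has one row
    per cluster with ``cluster_id``, ``size`` and, when ``values`` is given,
    peak coordinate and peak statistic (largest ``|value|`` in the cluster).
    """
    arr = np.asarray(binary_map)
    if arr.ndim != 3:
        raise ValidationError("binary map must be 3D")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError(f"map must be binary, found values {uniq[:10]}")
    arr = arr.astype(bool)
    raw, n = ndimage.label(arr, structure=_structure(connectivity))

    rows = []
    labels = np.zeros_like(raw)
    if n:
        # scipy labels in raster order of some internal scan; re-id clusters
        # by the lexicographic first voxel for a deterministic contract
        flat_first = ndimage.minimum(
            np.arange(raw.size).reshape(raw.shape), raw, index=np.arange(1, n + 1)
        )
        order = np.argsort(flat_first)
        sizes = ndimage.sum_labels(arr, raw, index=np.arange(1, n + 1))
        for new_id, old_idx in enumerate(order, start=1):
            old = old_idx + 1
            labels[raw == old] = new_id
            row = {"cluster_id": new_id, "size": int(sizes[old_idx])}
            if values is not None:
                vals = np.where(raw == old, np.abs(values), -np.inf)
                peak = np.unravel_index(np.argmax(vals), vals.shape)
                row["peak_x"], row["peak_y"], row["peak_z"] = map(int, peak)
                row["peak_stat"] = float(values[peak])
            if sign is not None:
                row["sign"] = sign
            rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "size"]
        + (["peak_x", "peak_y", "peak_z", "peak_stat"] if values is not None else [])
        + (["sign"] if sign is not None else []),
    )
    return labels, table


def _smooth_null_field(rng, shape, voxel_size_mm, fwhm_mm):
    field = rng.standard_normal(shape)
    if fwhm_mm and fwhm_mm > 0:
        sigma_vox = [
            fwhm_mm / (np.sqrt(8 * np.log(2)) * vs) for vs in voxel_size_mm
        ]
        field = ndimage.gaussian_filter(field, sigma=sigma_vox)
    return field


@dataclass
class NullCalibration:
    """Result of a Monte-Carlo cluster-extent calibration."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    fwhm_mm: float
    voxel_p: float
    two_sided: bool
    connectivity: str
    alpha: float
    n_iterations: int
    seed: int
    max_cluster_sizes: np.ndarray
    k_alpha: int

    def exceedance_probability(self, k: int) -> float:
        """Empirical P(max null cluster size >= k)."""
        return float(np.mean(self.max_cluster_sizes >= k))

    def to_json(self, path) -> None:
        d = asdict(self)
        d["max_cluster_sizes"] = np.asarray(self.max_cluster_sizes).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NullCalibration":
        with open(path) as fh:
            d = json.load(fh)
        d["max_cluster_sizes"] = np.asarray(d["max_cluster_sizes"], dtype=int)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        return cls(**d)


def simulate_cluster_null(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    mask: np.ndarray | None,
    fwhm_mm: float,
    voxel_p: float = 0.01,
    two_sided: bool = True,
    n_iterations: int = 1000,
    connectivity: str = "faces+edges+corners",
    alpha: float = 0.05,
    seed: int = 0,
) -> NullCalibration:
    """Calibrate the cluster-extent threshold on smooth Gaussian null fields.

    Each iteration draws white Gaussian noise on the grid, smooths it to the
    stated FWHM, standardizes it within the mask, thresholds at the normal
    quantile matching ``voxel_p`` (both tails when two-sided, clustered per
    sign) and records the maximum cluster size.  ``k_alpha`` is the smallest
    extent ``k`` with empirical P(max cluster >= k) <= alpha.
    """
    if n_iterations < 100:
        raise ConfigurationError("n_iterations must be >= 100")
    if not 0 < voxel_p < 1:
        raise ConfigurationError("voxel_p must lie in (0, 1)")
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(grid_shape):
        raise ValidationError(f"mask shape {mask.shape} != grid {tuple(grid_shape)}")
    if not mask.any():
        raise ValidationError("mask is empty")
    fwhm_eff = fwhm_mm
    if fwhm_mm and fwhm_mm < min(voxel_size_mm):
        import warnings

        warnings.warn(
            f"FWHM {fwhm_mm} mm below voxel size {min(voxel_size_mm)} mm; "
            "smoothing skipped",
            stacklevel=2,
        )
        fwhm_eff = 0.0

    z = stats.norm.ppf(1 - voxel_p / 2) if two_sided else stats.norm.ppf(1 - voxel_p)
    struct = _structure(connectivity)
    rng = np.random.default_rng(seed)
    maxima = np.zeros(n_iterations, dtype=int)
    for it in range(n_iterations):
        field = _smooth_null_field(rng, tuple(grid_shape), voxel_size_mm, fwhm_eff)
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        biggest = 0
        tails = (field >= z, field <= -z) if two_sided else (field >= z,)
        for tail in tails:
            tail = tail & mask
            if tail.any():
                lab, n = ndimage.label(tail, structure=struct)
                if n:
                    sizes = ndimage.sum_labels(tail, lab, index=np.arange(1, n + 1))
                    biggest = max(biggest, int(sizes.max()))
        maxima[it] = biggest

    # smallest k with empirical exceedance <= alpha
    k = 1
    while np.mean(maxima >= k) > alpha:
        k += 1
    return NullCalibration(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=tuple(voxel_size_mm),
        fwhm_mm=float(fwhm_mm),
        voxel_p=float(voxel_p),
        two_sided=bool(two_sided),
        connectivity=connectivity,
        alpha=float(alpha),
        n_iterations=int(n_iterations),
        seed=int(seed),
        max_cluster_sizes=maxima,
        k_alpha=int(k),
    )


def apply_cluster_threshold(
    statmap: StatMap,
    voxel_p: float = 0.01,
    k: int = 1,
    connectivity: str = "faces+edges+corners",
    two_sided: bool = True,
) -> tuple[StatMap, pd.DataFrame]:
    """Threshold a t map at ``voxel_p`` and remove clusters smaller than ``k``.

    Voxels at exactly the threshold are retained (>= comparison).  Positive
    and negative clusters are labeled and reported separately; the returned
    map is zero outside surviving clusters.
    """
    if statmap.df is None:
        raise ValidationError("statmap needs df for the p -> t conversion")
    if k < 1:
        raise ValidationError("cluster extent k must be >= 1")
    thr = (
        stats.t.ppf(1 - voxel_p / 2, statmap.df)
        if two_sided
        else stats.t.ppf(1 - voxel_p, statmap.df)
    )
    vals = np.where(statmap.valid, statmap.values, 0.0)
    vals = np.nan_to_num(vals, nan=0.0)

    out = np.zeros_like(vals)
    tables = []
    tails = [("positive", vals >= thr)]
    if two_sided:
        tails.append(("negative", vals <= -thr))
    next_id = 0
    for sign, tail in tails:
        labels, table = label_clusters(
            tail.astype(np.int8), connectivity=connectivity, values=vals, sign=sign
        )
        keep = table[table["size"] >= k]
        for _, row in keep.iterrows():
            out[labels == row["cluster_id"]] = vals[labels == row["cluster_id"]]
        if len(keep):
            keep = keep.copy()
            keep["cluster_id"] = np.arange(next_id + 1, next_id + 1 + len(keep))
            next_id += len(keep)
            tables.append(keep)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["cluster_id", "size", "peak_x", "peak_y", "peak_z",
                     "peak_stat", "sign"]
        )
    )
    thresholded = StatMap(
        values=out,
        stat_kind=statmap.stat_kind,
        df=statmap.df,
        voxel_size_mm=statmap.voxel_size_mm,
        affine=statmap.affine,
        valid=statmap.valid.copy(),
    )
    return thresholded, table


def restrict_to_roi(statmap: StatMap, roi_mask: np.ndarray) -> StatMap:
    """Confine a statistic map to an ROI (voxels outside become NaN/invalid).

    Cluster calibration for an ROI analysis should be re-run with the ROI as
    the mask: a smaller search volume yields a smaller extent threshold.
    """
    roi = np.asarray(roi_mask).astype(bool)
    if roi.shape != statmap.shape:
        raise ValidationError(
            f"ROI grid {roi.shape} does not match map grid {statmap.shape}"
        )
    if not (roi & statmap.valid).any():
        raise ValidationError("ROI does not intersect the valid map domain")
    vals = np.where(roi, statmap.values, np.nan)
    return StatMap(
        values=vals,
        stat_kind=statmap.stat_kind,
        df=statmap.df,
        voxel_size_mm=statmap.voxel_size_mm,
        affine=statmap.affine,
        valid=statmap.valid & roi,
    )
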