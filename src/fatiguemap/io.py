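"""NIfTI and gradient-table I/O plus pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import nibabel as nib
import yaml

from .errors import ConfigurationError, ValidationError


def write_volume(data: np.ndarray, path, voxel_size_mm=(3.0, 3.0, 3.0),
                 affine: np.ndarray | None = None) -> None:
    """Write a 3D/4D array as NIfTI-1 (gzipped or plain by extension)."""
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_size_mm) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI volume; returns (data, voxel_size_mm, affine)."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"volume not found: {p}")
    try:
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # malformed file
        raise ValidationError(f"cannot read volume {p}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms), img.affine


def write_bvals_bvecs(bvals, bvecs, bvals_path, bvecs_path) -> None:
    """Write FSL-dialect gradient tables: bvals one row; bvecs one row per axis."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    with open(bvals_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in bvals) + "\n")
    with open(bvecs_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.8f}" for v in bvecs[:, axis]) + "\n")


def read_bvals_bvecs(bvals_path, bvecs_path):
    """Read FSL-dialect bvals/bvecs; returns (bvals (n,), bvecs (n, 3))."""
    try:
        bvals = np.loadtxt(bvals_path, ndmin=1)
        bvecs = np.loadtxt(bvecs_path, ndmin=2)
    except Exception as exc:
        raise ValidationError(f"cannot read gradient tables: {exc}") from exc
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValidationError(
            f"bvecs shape {bvecs.shape} inconsistent with {bvals.size} b-values"
        )
    return bvals, bvecs


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated configuration for the experiment drivers.

    Paths are resolved relative to the config file's directory when loaded
    from YAML.  Unknown keys are rejected.
    """

    cohort_dir: str = "cohort"
    out_dir: str = "out"
    # paradigm / design
    tr_s: float = 2.0
    n_volumes_per_run: int = 135
    n_discard: int = 5
    detrend: bool = True
    center_amplitudes: bool = False
    smoothing_fwhm_mm: float = 0.0  # pre-GLM BOLD smoothing (off)
    map_smoothing_fwhm_mm: float = 6.0  # subject beta maps before group stats
    # HRF
    hrf_shape: float = 8.6
    hrf_scale_s: float = 0.547
    # cluster inference
    voxel_p: float = 0.01
    alpha: float = 0.05
    cluster_fwhm_mm: float = 6.0
    cluster_iterations: int = 1000
    connectivity: str = "faces+edges+corners"
    two_sided: bool = True
    roi_path: str | None = None
    use_covariates: bool = True
    # DTI
    weighted_tensor_fit: bool = False
    dti_group: str = "MS"
    fss_attribute: str = "fss_total"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.voxel_p < 1:
            raise ConfigurationError("voxel_p must lie in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.cluster_iterations < 100:
            raise ConfigurationError("cluster_iterations must be >= 100")
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        p = Path(path)
        with open(p) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        cfg = cls(**raw)
        for key in ("cohort_dir", "out_dir", "roi_path"):
            val = getattr(cfg, key)
            if val and not Path(val).is_absolute():
                setattr(cfg, key, str((p.parent / val)))
        return cfg
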