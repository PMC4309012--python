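"""EPI distortion correction by bidirectional elastic registration.

Perfusion and diffusion (EPI) volumes are geometrically warped relative
to structural scans by eddy currents.  The correction registers the
undistorted structural volume (target) with a pre-contrast perfusion or
b=0 diffusion volume (source) using a multi-resolution dense elastic
model (symmetric-forces demons: intensity-difference forces with
Gaussian smoothing of the displacement field), section by axial
section, in *both* directions, and couples the two results with an
explicit inverse-consistency averaging step.  The returned
:class:`~mslesion.fields.DeformationField` carries the forward
(source->target) and inverse (target->source) mappings plus the
measured consistency residual.

The dissimilarity is the intensity difference after per-volume
normalization, appropriate when source and target have monotone
intensity correspondence (true of the phantom; real multi-contrast
pairs would need a mutual-information front end).

Quantification never interpolates parametric values: ROIs drawn on the
target image are carried through the *inverse* mapping (nearest
neighbour) onto the source grid, and CBV/FA statistics are read off the
original, unresampled maps there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .fields import (
    DeformationField,
    composition_residual,
    invert_displacement,
    warp_volume,
)
from .grids import VolumeGrid

__all__ = [
    "RegistrationConfig",
    "register_elastic",
    "transform_rois_inverse",
    "sample_map_in_rois",
    "ROIStats",
]


@dataclass
class RegistrationConfig:
    """Hyperparameters of the slice-wise elastic registration.

    Defaults were chosen by phantom-recovery performance (field error
    and ROI overlap on studies warped by known fields) and are logged
    with every run.  ``smoothing_sigma_vox`` is the Gaussian
    regularization of the displacement field — larger values give
    smoother, lower-order fields.
    """

    smoothing_sigma_vox: float = 2.0
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    n_iterations: int = 100
    symmetrize: bool = True  # inverse-consistency averaging of the two directions
    histogram_match: bool = True  # match source intensities to the target first
    consistency_tol_vox: float = 0.5

    def as_dict(self) -> dict:
        return {
            "smoothing_sigma_vox": self.smoothing_sigma_vox,
            "shrink_factors": list(self.shrink_factors),
            "n_iterations": self.n_iterations,
            "symmetrize": self.symmetrize,
            "histogram_match": self.histogram_match,
        }


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(img, [1, 99])
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _to_sitk(a2d: np.ndarray, spacing) -> sitk.Image:
    # arrays are (x, y); SimpleITK wants (row=y, col=x), hence the transpose
    img = sitk.GetImageFromArray(a2d.astype(np.float64).T)
    img.SetSpacing((float(spacing[0]), float(spacing[1])))
    return img


def _register_slice(
    fixed2d: np.ndarray, moving2d: np.ndarray, spacing, cfg: RegistrationConfig
) -> tuple[np.ndarray, float, float]:
    """2-D dense elastic registration of one axial section.

    Multi-resolution symmetric-forces demons: intensity-difference
    forces with Gaussian displacement-field smoothing, coarse-to-fine.
    Returns the displacement field (mm, pulling the moving image onto
    the fixed grid) and the mean squared difference before/after.
    """
    fixed = _to_sitk(fixed2d, spacing)
    moving = _to_sitk(moving2d, spacing)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(cfg.n_iterations)
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(cfg.smoothing_sigma_vox)

    field = None
    for shrink in cfg.shrink_factors:
        f = sitk.Shrink(fixed, [shrink] * 2)
        m = sitk.Shrink(moving, [shrink] * 2)
        if field is None:
            field = sitk.Image(f.GetSize(), sitk.sitkVectorFloat64, 2)
            field.CopyInformation(f)
        else:
            field = sitk.Cast(
                sitk.Resample(field, f, sitk.Transform(), sitk.sitkLinear),
                sitk.sitkVectorFloat64,
            )
        field = demons.Execute(f, m, field)
    if field.GetSize() != fixed.GetSize():
        field = sitk.Cast(
            sitk.Resample(field, fixed, sitk.Transform(), sitk.sitkLinear),
            sitk.sitkVectorFloat64,
        )

    before = float(
        sitk.GetArrayFromImage(
            sitk.SquaredDifference(fixed, sitk.Resample(moving, fixed))
        ).mean()
    )
    warped = sitk.Warp(moving, field, outputSize=fixed.GetSize(),
                       outputSpacing=fixed.GetSpacing())
    after = float(
        sitk.GetArrayFromImage(sitk.SquaredDifference(fixed, warped)).mean()
    )

    disp = sitk.GetArrayFromImage(field)  # (y, x, 2), components in physical mm
    disp = np.transpose(disp, (1, 0, 2))  # -> (x, y, 2)
    return disp, before, after


def register_elastic(
    source: VolumeGrid,
    target: VolumeGrid,
    config: RegistrationConfig | None = None,
) -> DeformationField:
    """Bidirectional slice-wise elastic registration of an EPI source
    volume (pre-contrast perfusion or b=0 diffusion) onto a structural
    target.

    Both directions are optimized; when ``symmetrize`` is set the pair
    is averaged with the numerical inverse of its counterpart, which
    enforces approximate inverse consistency.  The run records the
    per-slice similarity change and raises no error on a slice that
    fails to improve — it is reported in ``field.improvement``.
    """
    cfg = config or RegistrationConfig()
    if source.shape != target.shape:
        raise ValueError("source/target fields of view do not overlap on a common grid")
    nx, ny, nz = source.shape
    src = _normalize(source.data)
    tgt = _normalize(target.data)
    if cfg.histogram_match:
        si = sitk.GetImageFromArray(src.T.copy())
        ti = sitk.GetImageFromArray(tgt.T.copy())
        si = sitk.HistogramMatching(
            si, ti, numberOfHistogramLevels=256, numberOfMatchPoints=16
        )
        src = sitk.GetArrayFromImage(si).T
    fwd = np.zeros((nx, ny, nz, 2))
    inv = np.zeros((nx, ny, nz, 2))
    improvements = []
    for k in range(nz):
        # forward: fixed=target, moving=source -> pulls source onto target grid
        d_f, b_f, a_f = _register_slice(tgt[..., k], src[..., k], source.voxel_size, cfg)
        d_i, b_i, a_i = _register_slice(src[..., k], tgt[..., k], source.voxel_size, cfg)
        fwd[..., k, :] = d_f
        inv[..., k, :] = d_i
        improvements.append(
            {"slice": k, "forward": (b_f, a_f), "inverse": (b_i, a_i),
             "improved": a_f <= b_f and a_i <= b_i}
        )
    if cfg.symmetrize:
        fwd = 0.5 * (fwd + invert_displacement(inv, source.voxel_size))
        inv = 0.5 * (inv + invert_displacement(fwd, source.voxel_size))
    fld = DeformationField(
        forward=fwd, inverse=inv, voxel_size=tuple(source.voxel_size),
        consistency_tol_vox=cfg.consistency_tol_vox,
    )
    fld.improvement = improvements
    fld.config = cfg.as_dict()
    return fld


def transform_rois_inverse(
    rois: np.ndarray, fld: DeformationField
) -> tuple[np.ndarray, dict[int, tuple[int, int]]]:
    """Carry a target-space label volume onto the source grid through
    the inverse mapping (nearest-neighbour, label-preserving).

    Returns the transformed labels and, per label, the (target, source)
    voxel counts so resampling-induced size changes are visible.
    """
    rois = np.asarray(rois)
    if rois.shape != fld.shape:
        raise ValueError("ROI volume and field grids do not match")
    out = warp_volume(rois.astype(float), fld.inverse, fld.voxel_size, order=0, cval=0)
    out = out.astype(rois.dtype)
    counts = {}
    for lab in np.unique(rois):
        if lab == 0:
            continue
        counts[int(lab)] = (int((rois == lab).sum()), int((out == lab).sum()))
    return out, counts


@dataclass
class ROIStats:
    label: int
    mean: float
    sd: float
    n: int
    n_invalid: int

    @property
    def empty(self) -> bool:
        return self.n == 0


def sample_map_in_rois(
    map_source_space: VolumeGrid, rois_source_space: np.ndarray
) -> dict[int, ROIStats]:
    """Per-ROI mean/SD/count on the original (unresampled) map.

    Invalid (NaN) voxels are excluded and counted; an ROI consisting
    solely of invalid voxels is flagged empty rather than reported as
    zero.
    """
    rois = np.asarray(rois_source_space)
    if rois.shape != map_source_space.shape:
        raise ValueError("ROI volume and map grids do not match")
    data = map_source_space.data
    out: dict[int, ROIStats] = {}
    for lab in np.unique(rois):
        if lab == 0:
            continue
        vals = data[rois == lab]
        finite = vals[np.isfinite(vals)]
        out[int(lab)] = ROIStats(
            label=int(lab),
            mean=float(finite.mean()) if finite.size else float("nan"),
            sd=float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
            n=int(finite.size),
            n_invalid=int(vals.size - finite.size),
        )
    return out
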