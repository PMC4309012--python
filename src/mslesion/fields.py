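"""Dense deformation fields and warping utilities.

Echo-planar (perfusion/diffusion) images are geometrically distorted
relative to structural scans almost entirely within the axial plane, and
the registration that corrects them operates section by section.  Fields
are therefore stored as in-plane displacements, one 2-vector per voxel,
shape ``(nx, ny, nz, 2)``, in millimetres.

Conventions (pull-back resampling):

* ``forward`` maps the *target* (structural) grid into *source* (EPI)
  space: ``corrected(x) = source_img(x + forward(x)/voxel)``.  Applying
  it to a distorted EPI image yields the undistorted image.
* ``inverse`` maps the *source* grid into *target* space:
  ``roi_src(x) = roi_tgt(x + inverse(x)/voxel)``.  Applying it to
  target-space ROIs carries them onto the unresampled source maps.

A consistent pair satisfies ``forward(x + inverse(x)) + inverse(x) = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "DeformationField",
    "warp_volume",
    "invert_displacement",
    "jacobian_determinant",
    "composition_residual",
    "random_smooth_field",
]


def _as_vox(disp_mm: np.ndarray, voxel_size) -> np.ndarray:
    out = np.empty_like(disp_mm)
    out[..., 0] = disp_mm[..., 0] / voxel_size[0]
    out[..., 1] = disp_mm[..., 1] / voxel_size[1]
    return out


def warp_volume(
    data: np.ndarray,
    disp_mm: np.ndarray,
    voxel_size,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``data`` through an in-plane displacement field.

    ``out[i, j, k] = data[i + u_x, j + u_y, k]`` with ``u`` in voxels.
    ``order=0`` gives nearest-neighbour (label-safe) interpolation.
    """
    data = np.asarray(data, dtype=float)
    if disp_mm.shape[:3] != data.shape:
        raise ValueError("field and volume grids do not match")
    disp = _as_vox(disp_mm, voxel_size)
    nx, ny, nz = data.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    out = np.empty_like(data)
    for k in range(nz):
        coords = np.stack([ii + disp[..., k, 0], jj + disp[..., k, 1]])
        out[..., k] = ndimage.map_coordinates(
            data[..., k], coords, order=order, mode="constant", cval=cval
        )
    return out


def _sample_field(disp_vox: np.ndarray, pts_x: np.ndarray, pts_y: np.ndarray, k: int) -> np.ndarray:
    coords = np.stack([pts_x, pts_y])
    ux = ndimage.map_coordinates(disp_vox[..., k, 0], coords, order=1, mode="nearest")
    uy = ndimage.map_coordinates(disp_vox[..., k, 1], coords, order=1, mode="nearest")
    return np.stack([ux, uy], axis=-1)


def invert_displacement(
    disp_mm: np.ndarray,
    voxel_size,
    n_iter: int = 30,
    tol_vox: float = 1e-3,
) -> np.ndarray:
    """Numerically invert a displacement field by fixed-point iteration.

    Solves ``v(x) = -u(x + v(x))`` slice-wise; converges for the smooth,
    sub-voxel-gradient fields used here.
    """
    disp = _as_vox(disp_mm, voxel_size)
    nx, ny, nz, _ = disp.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    inv = np.zeros_like(disp)
    for k in range(nz):
        v = np.zeros((nx, ny, 2))
        for _ in range(n_iter):
            u_at = _sample_field(disp, ii + v[..., 0], jj + v[..., 1], k)
            v_new = -u_at
            delta = np.max(np.abs(v_new - v))
            v = v_new
            if delta < tol_vox:
                break
        inv[..., k, :] = v
    out = np.empty_like(inv)
    out[..., 0] = inv[..., 0] * voxel_size[0]
    out[..., 1] = inv[..., 1] * voxel_size[1]
    return out


def jacobian_determinant(disp_mm: np.ndarray, voxel_size) -> np.ndarray:
    """Per-voxel determinant of the in-plane Jacobian of ``x + u(x)``."""
    disp = _as_vox(disp_mm, voxel_size)
    dux_dx = np.gradient(disp[..., 0], axis=0)
    dux_dy = np.gradient(disp[..., 0], axis=1)
    duy_dx = np.gradient(disp[..., 1], axis=0)
    duy_dy = np.gradient(disp[..., 1], axis=1)
    return (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx


def composition_residual(
    fwd_mm: np.ndarray, inv_mm: np.ndarray, voxel_size
) -> np.ndarray:
    """Magnitude (voxels) of ``forward(x + inverse(x)) + inverse(x)``."""
    fwd = _as_vox(fwd_mm, voxel_size)
    inv = _as_vox(inv_mm, voxel_size)
    nx, ny, nz, _ = fwd.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    res = np.empty((nx, ny, nz))
    for k in range(nz):
        f_at = _sample_field(fwd, ii + inv[..., k, 0], jj + inv[..., k, 1], k)
        res[..., k] = np.hypot(
            f_at[..., 0] + inv[..., k, 0], f_at[..., 1] + inv[..., k, 1]
        )
    return res


@dataclass
class DeformationField:
    """Paired forward/inverse dense in-plane displacement fields (mm).

    ``forward`` resamples source(EPI)-space images onto the target
    (structural) grid; ``inverse`` resamples target-space labels onto
    the source grid.  See the module docstring for exact conventions.
    """

    forward: np.ndarray
    inverse: np.ndarray
    voxel_size: tuple[float, float, float]
    control_spacing_mm: float = float("nan")
    consistency_tol_vox: float = 0.5

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.inverse = np.asarray(self.inverse, dtype=float)
        if self.forward.shape != self.inverse.shape or self.forward.shape[-1] != 2:
            raise ValueError("forward/inverse must be (nx, ny, nz, 2) and match")

    @classmethod
    def identity(cls, shape, voxel_size) -> "DeformationField":
        z = np.zeros(tuple(shape) + (2,))
        return cls(z, z.copy(), tuple(voxel_size))

    @classmethod
    def from_forward(cls, forward_mm: np.ndarray, voxel_size, **kw) -> "DeformationField":
        inv = invert_displacement(forward_mm, voxel_size)
        return cls(forward_mm, inv, tuple(voxel_size), **kw)

    @property
    def shape(self):
        return self.forward.shape[:3]

    def consistency_residual(self, mask: np.ndarray | None = None) -> float:
        res = composition_residual(self.forward, self.inverse, self.voxel_size)
        if mask is not None:
            res = res[mask]
        return float(np.max(res)) if res.size else 0.0

    def check_invertible(self, mask: np.ndarray | None = None) -> None:
        for name, disp in (("forward", self.forward), ("inverse", self.inverse)):
            det = jacobian_determinant(disp, self.voxel_size)
            if mask is not None:
                det = det[mask]
            if det.size and det.min() <= 0:
                raise ValueError(f"{name} field is not invertible (Jacobian <= 0)")

    def apply_forward(self, data: np.ndarray, order: int = 1) -> np.ndarray:
        return warp_volume(data, self.forward, self.voxel_size, order=order)

    def apply_inverse(self, data: np.ndarray, order: int = 1) -> np.ndarray:
        return warp_volume(data, self.inverse, self.voxel_size, order=order)

    # -- I/O ----------------------------------------------------------
    def to_nifti(self, forward_path: str | Path, inverse_path: str | Path) -> None:
        aff = np.diag(list(self.voxel_size) + [1.0])
        for path, disp in ((forward_path, self.forward), (inverse_path, self.inverse)):
            nib.save(nib.Nifti1Image(np.asarray(disp, dtype=np.float32), aff), str(path))

    @classmethod
    def from_nifti(cls, forward_path, inverse_path) -> "DeformationField":
        f = nib.load(str(forward_path))
        i = nib.load(str(inverse_path))
        vox = tuple(float(v) for v in np.abs(np.diag(f.affine)[:3]))
        return cls(np.asarray(f.dataobj, float), np.asarray(i.dataobj, float), vox)


def random_smooth_field(
    shape,
    voxel_size,
    amplitude_mm: float,
    rng: np.random.Generator,
    smooth_vox: float = 8.0,
    z_smooth_vox: float = 2.0,
    max_tries: int = 20,
) -> DeformationField:
    """Draw a smooth, invertible in-plane displacement field.

    White noise on the voxel grid is Gaussian-smoothed (strongly in
    plane, mildly through plane — eddy-current distortion varies slowly
    across sections) and scaled so the largest displacement magnitude
    equals ``amplitude_mm``.  Fields whose Jacobian determinant is not
    strictly positive are rejected and redrawn.
    """
    nx, ny, nz = shape
    for _ in range(max_tries):
        raw = rng.standard_normal((nx, ny, nz, 2))
        disp = np.stack(
            [
                ndimage.gaussian_filter(raw[..., c], (smooth_vox, smooth_vox, z_smooth_vox))
                for c in range(2)
            ],
            axis=-1,
        )
        mag = np.hypot(disp[..., 0], disp[..., 1]).max()
        if mag == 0:
            continue
        disp *= amplitude_mm / mag
        det = jacobian_determinant(disp, voxel_size)
        if det.min() > 0.05:
            fld = DeformationField.from_forward(disp, voxel_size)
            # the numerical inverse must itself be invertible
            if jacobian_determinant(fld.inverse, voxel_size).min() > 0:
                return fld
    raise RuntimeError("failed to draw an invertible field; lower the amplitude")
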