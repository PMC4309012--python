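"""Image containers shared by every stage of the pipeline.

A :class:`VolumeGrid` is a 3-D scalar image with voxel geometry; a
:class:`SeriesGrid` is a 4-D image (3-D + time, or 3-D + diffusion
encoding).  Invalid voxels are marked with NaN rather than magic numbers,
so statistics routines can exclude them with ``nan*`` reductions.

I/O goes through nibabel (NIfTI-1).  Axes follow nibabel's convention:
``data[i, j, k]`` with the affine mapping voxel indices to world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "SeriesGrid", "load_volume", "load_series"]


def _affine_from_geometry(voxel_size: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    aff[:3, 3] = origin
    return aff


@dataclass
class VolumeGrid:
    """A 3-D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    data:
        3-D float array; NaN marks invalid voxels.
    voxel_size:
        Edge lengths in mm, ``(dx, dy, dz)``.
    origin:
        World coordinate of voxel (0, 0, 0) in mm.
    units:
        Free-text unit label carried into NIfTI headers (e.g.
        ``"relative CBV"`` or ``"dimensionless"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.9375, 0.9375, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid requires 3-D data, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        return _affine_from_geometry(self.voxel_size, self.origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm^2 (axial sections are the x-y plane)."""
        return float(self.voxel_size[0] * self.voxel_size[1])

    def same_grid(self, other: "VolumeGrid | SeriesGrid") -> bool:
        return (
            self.shape[:3] == tuple(other.shape[:3])
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray, units: str | None = None) -> "VolumeGrid":
        return replace(self, data=data, units=self.units if units is None else units)

    # -- I/O ----------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header["descrip"] = self.units.encode()[:79]
        nib.save(img, str(path))


@dataclass
class SeriesGrid:
    """A 4-D image: 3-D volume stack over time or diffusion encoding.

    Exactly one of the two metadata flavours applies:

    * dynamic series -- ``frame_times`` (s, one per frame);
    * diffusion series -- ``bvals`` (s/mm^2) and ``bvecs`` (unit
      column vectors, shape ``(n_frames, 3)``; zero vectors for b=0).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.9375, 0.9375, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = ""
    frame_times: np.ndarray | None = None
    bvals: np.ndarray | None = None
    bvecs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"SeriesGrid requires 4-D data, got shape {self.data.shape}")
        n = self.data.shape[3]
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (n,):
                raise ValueError("frame_times length must equal the number of frames")
        if self.bvals is not None:
            self.bvals = np.asarray(self.bvals, dtype=float)
            self.bvecs = np.asarray(self.bvecs, dtype=float)
            if self.bvals.shape != (n,) or self.bvecs.shape != (n, 3):
                raise ValueError("bvals/bvecs must have one entry per frame")
            norms = np.linalg.norm(self.bvecs, axis=1)
            weighted = self.bvals > 0
            if not np.allclose(norms[weighted], 1.0, atol=1e-6):
                raise ValueError("gradient vectors must be unit norm where b > 0")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def affine(self) -> np.ndarray:
        return _affine_from_geometry(self.voxel_size, self.origin)

    def frame(self, index: int, units: str | None = None) -> VolumeGrid:
        return VolumeGrid(
            self.data[..., index],
            voxel_size=self.voxel_size,
            origin=self.origin,
            units=self.units if units is None else units,
        )

    def with_data(self, data: np.ndarray) -> "SeriesGrid":
        return replace(self, data=data)

    # -- I/O ----------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header["descrip"] = self.units.encode()[:79]
        if self.frame_times is not None and len(self.frame_times) > 1:
            img.header["pixdim"][4] = float(self.frame_times[1] - self.frame_times[0])
        nib.save(img, str(path))

    def save_gradients(self, bvec_path: str | Path, bval_path: str | Path) -> None:
        """Write FSL-style bvec/bval text files (3 rows / 1 row)."""
        if self.bvals is None or self.bvecs is None:
            raise ValueError("series carries no diffusion encoding")
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")


def _geometry_from_nifti(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    aff = img.affine
    vox = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    return vox, origin


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    vox, origin = _geometry_from_nifti(img)
    units = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), vox, origin, units)


def load_series(
    path: str | Path,
    frame_times: np.ndarray | None = None,
    bvec_path: str | Path | None = None,
    bval_path: str | Path | None = None,
) -> SeriesGrid:
    img = nib.load(str(path))
    vox, origin = _geometry_from_nifti(img)
    data = np.asarray(img.dataobj, dtype=float)
    bvals = bvecs = None
    if bval_path is not None:
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path).T
    if frame_times is None and bvals is None:
        dt = float(img.header["pixdim"][4])
        if dt > 0:
            frame_times = dt * np.arange(data.shape[3])
    return SeriesGrid(data, vox, origin, frame_times=frame_times, bvals=bvals, bvecs=bvecs)
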