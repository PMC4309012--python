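"""Mask-based brain volumetrics and the white-matter restriction.

Tissue segmentation itself is an input (any external tool, or the
phantom's ground truth); this module only performs the arithmetic on the
masks: volume = voxel count x voxel volume, with the composite ventricle
definitions (lateral = right + left; total = lateral + third + fourth),
and the restriction of lesion candidates to the WM region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .grids import VolumeGrid

__all__ = ["TissueMasks", "VolumetricsRecord", "compute_volumes", "restrict_to_wm"]


@dataclass
class TissueMasks:
    """Binary tissue/ventricle masks on the structural grid.

    WM/GM/CSF are mutually disjoint; the ventricle masks are mutually
    disjoint subsets of CSF.
    """

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    lateral_left: np.ndarray
    lateral_right: np.ndarray
    third: np.ndarray
    fourth: np.ndarray

    def __post_init__(self) -> None:
        for f in fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name), dtype=bool))
        if (self.wm & self.gm).any() or (self.wm & self.csf).any() or (self.gm & self.csf).any():
            raise ValueError("WM/GM/CSF masks must be mutually disjoint")
        vents = [self.lateral_left, self.lateral_right, self.third, self.fourth]
        total = sum(v.astype(int) for v in vents)
        if (total > 1).any():
            raise ValueError("ventricle masks must be mutually disjoint")

    @property
    def ventricles(self) -> np.ndarray:
        return self.lateral_left | self.lateral_right | self.third | self.fourth


@dataclass
class VolumetricsRecord:
    """Per-subject volumetrics in mm^3 (``*_ml`` properties give mL)."""

    wm_mm3: float
    gm_mm3: float
    lateral_ventricle_mm3: float
    third_ventricle_mm3: float
    fourth_ventricle_mm3: float

    @property
    def total_ventricle_mm3(self) -> float:
        # composite identity: total = lateral + third + fourth, exactly
        return self.lateral_ventricle_mm3 + self.third_ventricle_mm3 + self.fourth_ventricle_mm3

    @property
    def wm_ml(self) -> float:
        return self.wm_mm3 / 1000.0

    @property
    def gm_ml(self) -> float:
        return self.gm_mm3 / 1000.0

    @property
    def lateral_ventricle_ml(self) -> float:
        return self.lateral_ventricle_mm3 / 1000.0

    @property
    def total_ventricle_ml(self) -> float:
        return self.total_ventricle_mm3 / 1000.0

    def as_dict(self) -> dict:
        return {
            "wm_mm3": self.wm_mm3,
            "gm_mm3": self.gm_mm3,
            "lateral_ventricle_mm3": self.lateral_ventricle_mm3,
            "third_ventricle_mm3": self.third_ventricle_mm3,
            "fourth_ventricle_mm3": self.fourth_ventricle_mm3,
            "total_ventricle_mm3": self.total_ventricle_mm3,
        }


def compute_volumes(masks: TissueMasks, voxel_volume_mm3: float) -> VolumetricsRecord:
    """Exact voxel-count volumetry: volume = count x voxel volume.

    Equivalent to summing per-section areas and multiplying by the
    section thickness, since every voxel contributes area x thickness.
    """
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    count = lambda m: int(np.count_nonzero(m))
    return VolumetricsRecord(
        wm_mm3=count(masks.wm) * voxel_volume_mm3,
        gm_mm3=count(masks.gm) * voxel_volume_mm3,
        lateral_ventricle_mm3=(count(masks.lateral_left) + count(masks.lateral_right))
        * voxel_volume_mm3,
        third_ventricle_mm3=count(masks.third) * voxel_volume_mm3,
        fourth_ventricle_mm3=count(masks.fourth) * voxel_volume_mm3,
    )


def restrict_to_wm(candidates: np.ndarray, wm_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop candidate lesion voxels outside the WM mask.

    Returns the filtered binary mask and the number of removed voxels.
    """
    candidates = np.asarray(candidates, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if candidates.shape != wm_mask.shape:
        raise ValueError("candidate and WM masks must share a grid")
    kept = candidates & wm_mask
    return kept, int(candidates.sum() - kept.sum())
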