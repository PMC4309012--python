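"""Lesion identification, classification and ROI bookkeeping.

White-matter lesions are found as FLAIR hyperintensities exceeding a
local statistical threshold (NAWM mean + 2 SD), then classified with
the pre-/post-contrast T1 volumes:

* *active*: enhancing on post-contrast T1 (above NAWM mean + 2 SD on
  T1-post and brighter than its own pre-contrast signal);
* *T1-hypointense* ("black hole"): below NAWM mean - 2 SD on T1-pre;
* *T1-isointense*: FLAIR-hyperintense but unremarkable on T1.

Voxel precedence is active > hypointense > isointense, so a voxel that
is both enhancing and T1-dark counts as active.  A ring-enhancing
lesion therefore decomposes naturally into an active annulus plus a
core typed by its own T1-pre value.  All thresholds use strict
inequalities ("higher than" / "lower than").

Lesions smaller than ~5 pixels per section and lesions in close
proximity to CSF are flagged excluded (retained in the table, omitted
from totals) to suppress partial-volume artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .grids import VolumeGrid

__all__ = [
    "NAWMStats",
    "LesionRecord",
    "LesionTable",
    "estimate_nawm_stats",
    "iterative_nawm_stats",
    "detect_flair_hyperintensities",
    "detect_t1_hypointensities",
    "detect_enhancement",
    "classify_lesions",
    "apply_exclusions",
    "lesion_volumes",
    "spatial_relation",
    "neighborhood_nawm_stats",
    "evaluate_against_truth",
]

ACTIVE, HYPO, ISO = 1, 2, 3
TYPE_NAME = {ACTIVE: "active", HYPO: "t1_hypointense", ISO: "t1_isointense"}
TYPE_CODE = {v: k for k, v in TYPE_NAME.items()}


# ---------------------------------------------------------------------------
# NAWM reference statistics
# ---------------------------------------------------------------------------


@dataclass
class NAWMStats:
    """Normal-appearing-WM reference statistics, one (mean, SD) per slice.

    The sample excludes candidate-lesion voxels and a CSF dilation
    margin.  Slices whose sample is too small inherit the global
    statistics (or raise, if ``on_small="error"`` was requested).
    """

    mean: np.ndarray  # (nz,)
    sd: np.ndarray  # (nz,)
    n: np.ndarray  # (nz,) sample sizes
    sample_mask: np.ndarray
    global_mean: float
    global_sd: float

    def upper(self, k: float = 2.0) -> np.ndarray:
        """Per-slice threshold mean + k*SD, broadcastable to the volume."""
        return (self.mean + k * self.sd)[None, None, :]

    def lower(self, k: float = 2.0) -> np.ndarray:
        return (self.mean - k * self.sd)[None, None, :]


def _dilate_inplane(mask: np.ndarray, margin: int) -> np.ndarray:
    if margin <= 0 or not mask.any():
        return mask.astype(bool)
    struct = ndimage.generate_binary_structure(2, 2)  # 8-connectivity
    out = np.empty_like(mask, dtype=bool)
    for k in range(mask.shape[2]):
        out[..., k] = ndimage.binary_dilation(mask[..., k], struct, iterations=margin)
    return out


# 1 / Phi^-1(3/4): scales the median absolute deviation to the Gaussian SD
_MAD_SCALE = 1.4826022185056018


def _robust_stats(values: np.ndarray, estimator: str) -> tuple[float, float]:
    if estimator == "moment":
        return float(values.mean()), float(values.std(ddof=1))
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, _MAD_SCALE * mad


def estimate_nawm_stats(
    volume: VolumeGrid,
    wm_mask: np.ndarray,
    candidate_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    csf_margin: int = 2,
    min_voxels: int = 50,
    on_small: Literal["global", "error"] = "global",
    estimator: Literal["mad", "moment"] = "mad",
) -> NAWMStats:
    """Slice-wise NAWM mean/SD with candidate and CSF-margin exclusion.

    The default estimator is median / scaled MAD: for Gaussian data it
    estimates the same (mean, SD), but it stays anchored to the NAWM
    bulk even when undetected lesions contaminate a slice — without
    robustness, a heavily lesioned section can inflate the SD enough
    that its own lesions never cross the mean+2SD threshold.
    """
    data = volume.data
    sample = np.asarray(wm_mask, dtype=bool).copy()
    if candidate_mask is not None:
        sample &= ~np.asarray(candidate_mask, dtype=bool)
    if csf_mask is not None:
        sample &= ~_dilate_inplane(np.asarray(csf_mask, dtype=bool), csf_margin)
    total = sample.sum()
    if total < min_voxels:
        raise ValueError(f"only {total} NAWM sample voxels available (need {min_voxels})")
    gmean, gsd = _robust_stats(data[sample], estimator)
    nz = data.shape[2]
    mean = np.full(nz, gmean)
    sd = np.full(nz, gsd)
    n = np.zeros(nz, dtype=int)
    for k in range(nz):
        m = sample[..., k]
        n[k] = int(m.sum())
        if n[k] >= min_voxels:
            mean[k], sd[k] = _robust_stats(data[..., k][m], estimator)
        elif np.asarray(wm_mask)[..., k].any() and on_small == "error":
            raise ValueError(f"slice {k}: only {n[k]} NAWM sample voxels")
    if (sd <= 0).any():
        # degenerate (noiseless) reference: fall back to a tiny positive SD
        sd = np.where(sd > 0, sd, max(gsd, 1e-9))
    return NAWMStats(mean=mean, sd=sd, n=n, sample_mask=sample,
                     global_mean=gmean, global_sd=max(gsd, 1e-9))


def iterative_nawm_stats(
    volume: VolumeGrid,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray | None,
    detect,
    max_iter: int = 5,
    **kwargs,
) -> tuple[NAWMStats, np.ndarray, int]:
    """Alternate stats estimation and detection until the detected set
    stabilizes (fixed point); returns (stats, mask, iterations used).

    ``detect(volume, stats)`` must return a boolean candidate mask.
    """
    candidate = np.zeros(volume.shape, dtype=bool)
    stats = estimate_nawm_stats(volume, wm_mask, candidate, csf_mask, **kwargs)
    for it in range(1, max_iter + 1):
        mask = detect(volume, stats)
        if (mask == candidate).all():
            return stats, mask, it
        candidate = mask
        stats = estimate_nawm_stats(volume, wm_mask, candidate, csf_mask, **kwargs)
    return stats, candidate, max_iter


def neighborhood_nawm_stats(
    volume: VolumeGrid,
    component_mask: np.ndarray,
    wm_mask: np.ndarray,
    exclude_mask: np.ndarray | None = None,
    r_min_mm: float = 10.0,
    r_max_mm: float = 20.0,
    min_voxels: int = 50,
) -> tuple[float, float] | None:
    """Mean/SD of WM in a 10-20 mm annulus around one lesion candidate.

    Returns None when the annulus sample is too small (caller falls back
    to slice-wise statistics).
    """
    dist = ndimage.distance_transform_edt(~np.asarray(component_mask, bool),
                                          sampling=volume.voxel_size)
    sample = (dist >= r_min_mm) & (dist <= r_max_mm) & np.asarray(wm_mask, bool)
    if exclude_mask is not None:
        sample &= ~np.asarray(exclude_mask, bool)
    if sample.sum() < min_voxels:
        return None
    vals = volume.data[sample]
    return float(vals.mean()), float(vals.std(ddof=1))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _label_regions(mask: np.ndarray, connectivity: Literal["2d", "3d"]) -> tuple[np.ndarray, int]:
    """Connected components: 8-connectivity per axial slice (default,
    matching section-wise evaluation) or 26-connectivity in 3-D."""
    if connectivity == "3d":
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        return labels, n
    labels = np.zeros(mask.shape, dtype=np.int32)
    offset = 0
    for k in range(mask.shape[2]):
        lab = measure.label(mask[..., k], connectivity=2)
        nk = int(lab.max())
        labels[..., k] = np.where(lab > 0, lab + offset, 0)
        offset += nk
    return labels, offset


def detect_flair_hyperintensities(
    flair: VolumeGrid,
    stats: NAWMStats,
    wm_mask: np.ndarray,
    connectivity: Literal["2d", "3d"] = "2d",
) -> tuple[np.ndarray, np.ndarray, int]:
    """FLAIR voxels strictly above NAWM mean+2SD inside WM, labelled.

    Returns (mask, label volume, number of regions).  An empty result is
    valid (healthy controls).
    """
    mask = (flair.data > stats.upper(2.0)) & np.asarray(wm_mask, dtype=bool)
    labels, n = _label_regions(mask, connectivity)
    return mask, labels, n


def detect_t1_hypointensities(
    t1pre: VolumeGrid, stats: NAWMStats, wm_mask: np.ndarray
) -> np.ndarray:
    """T1-pre voxels strictly below NAWM mean-2SD inside WM."""
    return (t1pre.data < stats.lower(2.0)) & np.asarray(wm_mask, dtype=bool)


def detect_enhancement(
    t1pre: VolumeGrid,
    t1post: VolumeGrid,
    stats_post: NAWMStats,
    wm_mask: np.ndarray,
    require_increase: bool = True,
    diff_sd_factor: float = 2.0,
) -> np.ndarray:
    """Gadolinium-enhancing voxels on post-contrast T1.

    A voxel is enhanced when its T1-post signal is strictly above the
    NAWM mean+2SD *and* (by default) its post-pre difference exceeds
    ``diff_sd_factor`` times the SD of that difference in the NAWM
    sample — guarding against tissue that is bright on both T1 volumes.
    """
    if t1pre.shape != t1post.shape:
        raise ValueError("pre/post grids do not match")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    mask = (t1post.data > stats_post.upper(2.0)) & wm_mask
    if require_increase:
        diff = t1post.data - t1pre.data
        sample = stats_post.sample_mask
        sd_diff = float(diff[sample].std(ddof=1)) if sample.sum() > 1 else 0.0
        mean_diff = float(diff[sample].mean()) if sample.any() else 0.0
        mask &= diff > mean_diff + diff_sd_factor * max(sd_diff, 1e-9)
    return mask


# ---------------------------------------------------------------------------
# records and classification
# ---------------------------------------------------------------------------


@dataclass
class LesionRecord:
    """One typed lesion region (a connected FLAIR component may yield up
    to three records: its active, hypointense and isointense parts)."""

    lesion_id: int
    region_id: int
    lesion_type: str
    voxels: np.ndarray  # (n, 3) voxel indices
    n_voxels: int
    areas_mm2: dict[int, float]  # slice index -> cross-section area
    volume_mm3: float
    mean_cbv: float = np.nan
    sd_cbv: float = np.nan
    mean_fa: float = np.nan
    sd_fa: float = np.nan
    spatial_relation: str | None = None
    excluded: bool = False
    exclusion_reasons: tuple[str, ...] = ()


@dataclass
class LesionTable:
    """All lesion records of one subject plus grid geometry."""

    records: list[LesionRecord]
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    @property
    def retained(self) -> list[LesionRecord]:
        return [r for r in self.records if not r.excluded]

    def counts_by_type(self) -> dict[str, int]:
        out = {name: 0 for name in TYPE_NAME.values()}
        for r in self.retained:
            out[r.lesion_type] += 1
        return out

    def volumes_by_type(self) -> dict[str, float]:
        out = {name: 0.0 for name in TYPE_NAME.values()}
        for r in self.retained:
            out[r.lesion_type] += r.volume_mm3
        return out

    @property
    def combined_load_mm3(self) -> float:
        """T1-hypointense plus active lesion volume (the load index)."""
        v = self.volumes_by_type()
        return v["t1_hypointense"] + v["active"]

    @property
    def total_load_mm3(self) -> float:
        return sum(self.volumes_by_type().values())

    def label_volume(self) -> np.ndarray:
        """Typed label image: 1 active / 2 hypo / 3 iso, negated when
        excluded; 0 background."""
        out = np.zeros(self.grid_shape, dtype=np.int16)
        for r in self.records:
            code = TYPE_CODE[r.lesion_type]
            if r.excluded:
                code = -code
            out[tuple(r.voxels.T)] = code
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "lesion_id": r.lesion_id,
                    "region_id": r.region_id,
                    "type": r.lesion_type,
                    "n_voxels": r.n_voxels,
                    "volume_mm3": r.volume_mm3,
                    "n_slices": len(r.areas_mm2),
                    "mean_cbv": r.mean_cbv,
                    "sd_cbv": r.sd_cbv,
                    "mean_fa": r.mean_fa,
                    "sd_fa": r.sd_fa,
                    "spatial_relation": r.spatial_relation,
                    "excluded": r.excluded,
                    "exclusion_reasons": ";".join(r.exclusion_reasons),
                }
            )
        return pd.DataFrame(rows)


def _make_record(
    lesion_id: int,
    region_id: int,
    lesion_type: str,
    mask: np.ndarray,
    voxel_size,
) -> LesionRecord:
    voxels = np.argwhere(mask)
    pixel_area = voxel_size[0] * voxel_size[1]
    slices, counts = np.unique(voxels[:, 2], return_counts=True)
    areas = {int(k): float(c) * pixel_area for k, c in zip(slices, counts)}
    # volume = sum of per-slice areas x section thickness, exactly
    volume = sum(areas.values()) * voxel_size[2]
    return LesionRecord(
        lesion_id=lesion_id,
        region_id=region_id,
        lesion_type=lesion_type,
        voxels=voxels,
        n_voxels=len(voxels),
        areas_mm2=areas,
        volume_mm3=volume,
    )


def classify_lesions(
    flair_labels: np.ndarray,
    t1hypo_mask: np.ndarray,
    enhance_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    grid_shape: tuple[int, int, int] | None = None,
) -> LesionTable:
    """Assign every FLAIR-hyperintense voxel exactly one lesion type.

    Precedence is active > T1-hypointense > T1-isointense, applied
    within each labelled FLAIR region; each (region, type) pair with at
    least one voxel becomes a :class:`LesionRecord`.  A ring-enhancing
    region thereby splits into an active annulus and a separately-typed
    core.
    """
    flair_labels = np.asarray(flair_labels)
    if grid_shape is None:
        grid_shape = flair_labels.shape
    t1hypo_mask = np.asarray(t1hypo_mask, dtype=bool)
    enhance_mask = np.asarray(enhance_mask, dtype=bool)
    records: list[LesionRecord] = []
    next_id = 0
    for region_id in np.unique(flair_labels):
        if region_id == 0:
            continue
        region = flair_labels == region_id
        active = region & enhance_mask
        hypo = region & t1hypo_mask & ~active
        iso = region & ~active & ~hypo
        for type_name, mask in (
            ("active", active),
            ("t1_hypointense", hypo),
            ("t1_isointense", iso),
        ):
            if mask.any():
                records.append(
                    _make_record(next_id, int(region_id), type_name, mask, voxel_size)
                )
                next_id += 1
    return LesionTable(records=records, grid_shape=tuple(grid_shape), voxel_size=tuple(voxel_size))


def apply_exclusions(
    table: LesionTable,
    csf_mask: np.ndarray,
    min_area_mm2: float = 4.4,
    csf_margin: int = 2,
) -> LesionTable:
    """Flag partial-volume-prone records: sub-minimum cross-sections and
    CSF proximity.

    The area minimum is quantized to whole pixels
    (``min_pixels = round(min_area_mm2 / pixel_area)``, i.e. "less than
    5 pixels" at the default geometry): a record is flagged small when
    every one of its slice cross-sections is below the minimum.  Records
    intersecting the CSF mask dilated by ``csf_margin`` in-plane voxels
    are flagged as periventricular.  Flagged records are retained but
    omitted from all totals.
    """
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be non-negative")
    pixel_area = table.voxel_size[0] * table.voxel_size[1]
    min_pixels = int(round(min_area_mm2 / pixel_area))
    csf_near = _dilate_inplane(np.asarray(csf_mask, dtype=bool), csf_margin)
    new_records = []
    for r in table.records:
        reasons = list(r.exclusion_reasons)
        slice_counts = {k: a / pixel_area for k, a in r.areas_mm2.items()}
        if all(c < min_pixels for c in slice_counts.values()):
            reasons.append("min_area")
        if csf_near[tuple(r.voxels.T)].any():
            reasons.append("csf_proximity")
        new_records.append(
            replace(r, excluded=bool(reasons), exclusion_reasons=tuple(reasons))
        )
    return LesionTable(new_records, table.grid_shape, table.voxel_size)


@dataclass
class LesionVolumes:
    by_type: dict[str, float]
    combined_load_mm3: float  # hypointense + active only
    total_mm3: float
    counts: dict[str, int]


def lesion_volumes(table: LesionTable) -> LesionVolumes:
    """Per-type totals and the combined (hypo + active) lesion load.

    Volumes are section-area sums times slice thickness — exact integer
    voxel arithmetic, no tolerance.
    """
    v = table.volumes_by_type()
    return LesionVolumes(
        by_type=v,
        combined_load_mm3=v["t1_hypointense"] + v["active"],
        total_mm3=sum(v.values()),
        counts=table.counts_by_type(),
    )


@dataclass
class RelationSummary:
    n_active: int
    counts: dict[str, int]
    percentages: dict[str, float] | None  # None when no active lesions

    @property
    def defined(self) -> bool:
        return self.percentages is not None


def spatial_relation(
    table: LesionTable,
    t1hypo_mask: np.ndarray,
    adjacency_margin: int = 2,
    overlap_threshold: float = 0.5,
) -> RelationSummary:
    """Relate each retained active lesion to the T1-hypointense areas.

    overlapping: >= ``overlap_threshold`` of the active area lies on
    hypointense voxels; adjacent: not overlapping but within
    ``adjacency_margin`` in-plane voxels of a hypointense area;
    independent: neither.  Percentages are returned unrounded.
    """
    if adjacency_margin < 0:
        raise ValueError("adjacency margin must be >= 0")
    hypo = np.asarray(t1hypo_mask, dtype=bool)
    near = _dilate_inplane(hypo, adjacency_margin)
    counts = {"overlapping": 0, "adjacent": 0, "independent": 0}
    n_active = 0
    for r in table.records:
        if r.lesion_type != "active" or r.excluded:
            continue
        n_active += 1
        idx = tuple(r.voxels.T)
        frac = hypo[idx].mean()
        if frac >= overlap_threshold:
            rel = "overlapping"
        elif near[idx].any():
            rel = "adjacent"
        else:
            rel = "independent"
        r.spatial_relation = rel
        counts[rel] += 1
    if n_active == 0:
        return RelationSummary(0, counts, None)
    pct = {k: 100.0 * v / n_active for k, v in counts.items()}
    return RelationSummary(n_active, counts, pct)


# ---------------------------------------------------------------------------
# whole-study convenience chain
# ---------------------------------------------------------------------------


def run_classification(
    flair: VolumeGrid,
    t1pre: VolumeGrid,
    t1post: VolumeGrid,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    min_area_mm2: float = 4.4,
    csf_margin: int = 2,
    adjacency_margin: int = 2,
    overlap_threshold: float = 0.5,
    connectivity: Literal["2d", "3d"] = "2d",
) -> tuple[LesionTable, RelationSummary, dict]:
    """Full detection/classification chain for one subject.

    Iteratively estimates FLAIR NAWM statistics, detects and labels the
    hyperintensities, thresholds the T1 volumes, classifies, applies the
    exclusion rules and relates active to hypointense lesions.  Returns
    the lesion table, the relation summary and the intermediate masks.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    csf_mask = np.asarray(csf_mask, dtype=bool)

    def _detect(vol, st):
        return (vol.data > st.upper(2.0)) & wm_mask

    flair_stats, flair_mask, _ = iterative_nawm_stats(flair, wm_mask, csf_mask, _detect)
    flair_mask, flair_labels, _ = detect_flair_hyperintensities(
        flair, flair_stats, wm_mask, connectivity=connectivity
    )
    pre_stats = estimate_nawm_stats(t1pre, wm_mask, flair_mask, csf_mask)
    post_stats = estimate_nawm_stats(t1post, wm_mask, flair_mask, csf_mask)
    t1hypo = detect_t1_hypointensities(t1pre, pre_stats, wm_mask)
    enhance = detect_enhancement(t1pre, t1post, post_stats, wm_mask)
    table = classify_lesions(flair_labels, t1hypo, enhance, flair.voxel_size)
    table = apply_exclusions(table, csf_mask, min_area_mm2=min_area_mm2, csf_margin=csf_margin)
    relations = spatial_relation(
        table, t1hypo, adjacency_margin=adjacency_margin, overlap_threshold=overlap_threshold
    )
    masks = {
        "flair": flair_mask, "flair_labels": flair_labels,
        "t1hypo": t1hypo, "enhance": enhance,
        "flair_stats": flair_stats, "pre_stats": pre_stats, "post_stats": post_stats,
    }
    return table, relations, masks


# ---------------------------------------------------------------------------
# ground-truth scoring (phantom studies)
# ---------------------------------------------------------------------------


def evaluate_against_truth(table: LesionTable, truth) -> pd.DataFrame:
    """Score a lesion table against :class:`~mslesion.phantom.PhantomTruth`.

    Each ground-truth lesion contributes one unit per tissue type it
    contains (a ring contributes its annulus and its core separately).
    A unit agrees when the majority detected type over its voxels
    matches the true type.  Returns one row per unit with the truth and
    detected labels.
    """
    detected = table.label_volume()
    detected = np.where(detected > 0, detected, 0)  # excluded records -> undetected
    rows = []
    for les in truth.lesions:
        mine = truth.label_volume == 10 + les.lesion_id
        if les.true_type == "ring":
            units = [
                ("active", mine & (truth.type_volume == TYPE_CODE["active"])),
                (les.core_type, mine & (truth.type_volume == TYPE_CODE[les.core_type])),
            ]
        else:
            units = [(les.true_type, mine)]
        for unit_type, umask in units:
            if not umask.any():
                continue
            vals = detected[umask]
            vals = vals[vals > 0]
            if vals.size == 0:
                maj = "undetected"
            else:
                maj = TYPE_NAME[int(np.bincount(vals).argmax())]
            rows.append(
                {
                    "lesion_id": les.lesion_id,
                    "true_type": unit_type,
                    "detected_type": maj,
                    "agree": maj == unit_type,
                    "n_voxels": int(umask.sum()),
                }
            )
    return pd.DataFrame(rows)
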