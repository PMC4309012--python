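"""Multimodal digital brain phantom with ground-truth lesions.

The simulator produces co-registered T2-FLAIR, pre-/post-contrast T1,
DSC perfusion and diffusion series for a simplified supratentorial
brain: an elliptical brain outline with a cortical GM shell, a WM
interior, paired lateral ventricles plus third and fourth ventricles,
and spherical WM lesions of four phenotypes:

* ``active`` -- FLAIR-hyperintense, gadolinium-enhancing on post-T1;
* ``t1_hypointense`` -- FLAIR-hyperintense, dark on pre-contrast T1
  ("black hole");
* ``t1_isointense`` -- FLAIR-hyperintense, unremarkable on T1;
* ``ring`` -- enhancing annulus around a non-enhancing core whose
  pre-contrast T1 signal determines the core class.

Acquisition geometry defaults follow a 240 mm axial FOV on a 256-pixel
reconstruction grid (0.9375 mm in plane) with contiguous 4 mm sections.
Every generated study carries a :class:`PhantomTruth` with voxelwise
labels, true CBV/FA, the tissue masks, and the true deformation-field
pair, so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .fields import DeformationField, random_smooth_field
from .grids import SeriesGrid, VolumeGrid
from .morphometry import TissueMasks

__all__ = [
    "TissueParams",
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "EffectConfig",
    "SubjectRecord",
    "generate_structural",
    "generate_dsc",
    "generate_dti",
    "apply_synthetic_distortion",
    "generate_cohort",
    "cohort_truth_table",
    "build_truth",
    "place_lesions",
    "default_tissue_params",
    "fibonacci_directions",
    "eigenvalues_from_fa_md",
]

LesionType = Literal["active", "t1_hypointense", "t1_isointense", "ring"]

# voxelwise ground-truth class codes for lesion tissue
TYPE_CODE = {"active": 1, "t1_hypointense": 2, "t1_isointense": 3}


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass
class TissueParams:
    """Nominal signal statistics and true parametric values for one class.

    Means are arbitrary scanner units.  The SDs are *nominal*
    heterogeneity values used to validate lesion detectability margins;
    realized voxel noise is governed by ``PhantomSpec.noise_sigma``
    alone, so noiseless phantoms satisfy the threshold relations
    exactly.
    """

    flair: tuple[float, float]
    t1pre: tuple[float, float]
    t1post: tuple[float, float]
    cbv: float  # relative units (WM = 1)
    fa: float  # dimensionless, [0, 1)
    fiber: tuple[float, float, float] = (1.0, 0.0, 0.0)
    md: float = 0.7e-3  # mean diffusivity, mm^2/s
    dsc_s0: float = 100.0
    dti_s0: float = 100.0

    def __post_init__(self) -> None:
        for m in (self.flair, self.t1pre, self.t1post):
            if m[1] <= 0:
                raise ValueError("nominal signal SDs must be > 0")
        if not (0.0 <= self.fa < 1.0):
            raise ValueError("true FA must lie in [0, 1)")
        n = np.linalg.norm(self.fiber)
        if n > 0:
            self.fiber = tuple(np.asarray(self.fiber, float) / n)


def default_tissue_params() -> dict[str, TissueParams]:
    # EPI baseline (dsc_s0/dti_s0) contrasts are stylized to correspond
    # monotonically to FLAIR (dark ventricles), which lets the elastic
    # registration use an intensity-difference dissimilarity; real b=0
    # images have bright CSF and would need a mutual-information metric.
    return {
        "wm": TissueParams(flair=(100.0, 2.0), t1pre=(100.0, 2.0), t1post=(100.0, 2.0),
                           cbv=1.0, fa=0.45, fiber=(1.0, 0.0, 0.0), md=0.7e-3),
        "gm": TissueParams(flair=(115.0, 3.0), t1pre=(80.0, 3.0), t1post=(80.0, 3.0),
                           cbv=2.0, fa=0.10, fiber=(0.0, 1.0, 0.0), md=0.9e-3,
                           dsc_s0=110.0, dti_s0=110.0),
        "csf": TissueParams(flair=(30.0, 2.0), t1pre=(40.0, 2.0), t1post=(40.0, 2.0),
                            cbv=0.05, fa=0.02, md=3.0e-3, dsc_s0=25.0, dti_s0=25.0),
    }


# Lesion EPI baselines. The DSC baseline equals WM so the
# signal-level-dependent noise bias of the log-based Delta-R2* estimate
# cancels between lesion and WM ROIs; the diffusion b=0 baseline is
# mildly hyperintense (T2-weighted EPI shows MS lesions bright), which
# also anchors the elastic registration inside the WM.
LESION_DSC_S0 = 100.0
LESION_DTI_S0 = 112.0


# additive offsets relative to WM means (5 sigma at the default SNR ~20,
# i.e. conspicuous lesions whose per-voxel type misassignment rate under
# the 2-SD thresholds is ~0.1%), and true parametric values
DEFAULT_LESION_SIGNALS: dict[str, dict] = {
    "active": {"offsets": {"flair": 25.0, "t1pre": 0.0, "t1post": 30.0},
               "cbv": 1.4, "fa": 0.20, "md": 1.0e-3},
    "t1_hypointense": {"offsets": {"flair": 25.0, "t1pre": -25.0, "t1post": -25.0},
                       "cbv": 0.4, "fa": 0.15, "md": 1.2e-3},
    "t1_isointense": {"offsets": {"flair": 25.0, "t1pre": 0.0, "t1post": 0.0},
                      "cbv": 1.0, "fa": 0.45, "md": 0.8e-3},
}


@dataclass
class LesionSpec:
    """One spherical lesion: position, extent, phenotype and signals.

    ``signal_offsets`` are additive offsets relative to the WM means
    (for a ring lesion they describe the enhancing annulus and
    ``core_offsets``/``core_type`` the core).
    """

    center: tuple[float, float, float]  # voxel coordinates
    radius_mm: float
    true_type: LesionType
    ring_thickness_mm: float | None = None
    signal_offsets: dict[str, float] | None = None
    lesion_cbv: float | None = None
    lesion_fa: float | None = None
    core_type: Literal["t1_hypointense", "t1_isointense"] = "t1_hypointense"
    core_offsets: dict[str, float] | None = None
    core_cbv: float | None = None
    core_fa: float | None = None
    md: float | None = None

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.true_type == "ring":
            if self.ring_thickness_mm is None or not (
                0 < self.ring_thickness_mm < self.radius_mm
            ):
                raise ValueError("ring lesions need 0 < ring_thickness < radius")
            base = DEFAULT_LESION_SIGNALS["active"]
            core = DEFAULT_LESION_SIGNALS[self.core_type]
            if self.core_offsets is None:
                self.core_offsets = dict(core["offsets"])
            if self.core_cbv is None:
                self.core_cbv = core["cbv"]
            if self.core_fa is None:
                self.core_fa = core["fa"]
        else:
            base = DEFAULT_LESION_SIGNALS[self.true_type]
        if self.signal_offsets is None:
            self.signal_offsets = dict(base["offsets"])
        if self.lesion_cbv is None:
            self.lesion_cbv = base["cbv"]
        if self.lesion_fa is None:
            self.lesion_fa = base["fa"]
        if self.md is None:
            self.md = base["md"]

    def validate_against(self, tissue: dict[str, TissueParams], noise_sigma: float) -> None:
        """Reject configurations that contradict the declared phenotype.

        The local-threshold detector can only see a lesion whose FLAIR
        signal clears mean+2SD of NAWM, and can only type it correctly
        if the T1 offsets fall on the declared side of the +-2SD bands.
        """
        wm = tissue["wm"]
        sd = lambda nominal: max(nominal, noise_sigma)
        off = self.signal_offsets
        if off.get("flair", 0.0) <= 2.0 * sd(wm.flair[1]):
            raise ValueError(
                f"lesion at {self.center}: FLAIR offset {off.get('flair')} does not "
                "clear the mean+2SD hyperintensity threshold (undetectable)"
            )
        t1pre_off = off.get("t1pre", 0.0)
        post_excess = off.get("t1post", 0.0) - t1pre_off
        kind = "active" if self.true_type == "ring" else self.true_type
        if kind == "t1_hypointense":
            if t1pre_off >= -2.0 * sd(wm.t1pre[1]):
                raise ValueError("declared t1_hypointense but T1-pre offset not below mean-2SD")
        elif kind == "t1_isointense":
            if abs(t1pre_off) >= 2.0 * sd(wm.t1pre[1]):
                raise ValueError("declared t1_isointense but T1-pre offset outside +-2SD band")
            if off.get("t1post", 0.0) > 2.0 * sd(wm.t1post[1]) and post_excess > 0:
                raise ValueError("declared t1_isointense but T1-post offset is enhancing")
        elif kind == "active":
            if off.get("t1post", 0.0) <= 2.0 * sd(wm.t1post[1]) or post_excess <= 0:
                raise ValueError("declared active/ring but T1-post offset is not enhancing")
        if self.true_type == "ring":
            coff = self.core_offsets
            if self.core_type == "t1_hypointense" and coff.get("t1pre", 0.0) >= -2.0 * sd(wm.t1pre[1]):
                raise ValueError("ring core declared t1_hypointense but core T1-pre offset too high")


@dataclass
class PhantomSpec:
    """Complete description of one synthetic subject acquisition."""

    grid_shape: tuple[int, int, int] = (64, 64, 8)
    voxel_size: tuple[float, float, float] = (0.9375, 0.9375, 4.0)
    tissue_params: dict[str, TissueParams] = field(default_factory=default_tissue_params)
    lesion_specs: list[LesionSpec] = field(default_factory=list)
    deformation_amplitude_mm: float = 0.0
    noise_sigma: float = 0.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    rng_seed: int = 0
    ventricle_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        nx, ny, nz = self.grid_shape
        for les in self.lesion_specs:
            rx = les.radius_mm / self.voxel_size[0]
            if not (
                rx <= les.center[0] <= nx - 1 - rx and rx <= les.center[1] <= ny - 1 - rx
            ):
                raise ValueError(f"lesion at {les.center} does not fit inside the grid")

    @property
    def n_slices(self) -> int:
        return self.grid_shape[2]

    def validate_lesions(self) -> None:
        for les in self.lesion_specs:
            les.validate_against(self.tissue_params, self.noise_sigma)

    def _streams(self) -> dict[str, np.random.Generator]:
        """Independent, purpose-keyed RNG streams derived from rng_seed."""
        ss = np.random.SeedSequence(self.rng_seed)
        keys = ("structural", "dsc", "dti", "field")
        children = ss.spawn(len(keys))
        return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


@dataclass
class LesionTruth:
    lesion_id: int
    true_type: LesionType
    center: tuple[float, float, float]
    radius_mm: float
    n_voxels: int
    volume_mm3: float
    cbv: float
    fa: float
    core_type: str | None = None
    n_core_voxels: int = 0
    true_relation: str | None = None  # for active lesions: how it was placed


@dataclass
class PhantomTruth:
    """Voxelwise and per-lesion ground truth for one phantom subject."""

    label_volume: np.ndarray  # 0 bg, 1 WM, 2 GM, 3 CSF, 10+i lesion i
    type_volume: np.ndarray  # 0 none, 1 active, 2 hypo, 3 iso (lesion tissue only)
    masks: TissueMasks
    lesions: list[LesionTruth]
    true_cbv: np.ndarray
    true_fa: np.ndarray
    fiber: np.ndarray  # (nx, ny, nz, 3) principal direction
    md: np.ndarray
    field: DeformationField
    voxel_size: tuple[float, float, float]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def lesion_mask(self, lesion_id: int) -> np.ndarray:
        return self.label_volume == 10 + lesion_id


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------


def _build_anatomy(
    grid_shape, voxel_size, ventricle_scale: float
) -> dict[str, np.ndarray]:
    """Deterministic tissue geometry: brain ellipse, GM shell, ventricles."""
    nx, ny, nz = grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ax, ay = 0.42 * nx, 0.45 * ny
    rho = np.sqrt(((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2)
    brain2d = rho <= 1.0
    gm2d = brain2d & (rho > 0.80)
    interior2d = rho <= 0.80

    def ellipse(cx_, cy_, ax_, ay_):
        return (((ii - cx_) / ax_) ** 2 + ((jj - cy_) / ay_) ** 2) <= 1.0

    s = float(ventricle_scale)
    lat_ax, lat_ay = 0.055 * nx * s, 0.16 * ny * s
    lat_off = 0.10 * nx
    lat_l2d = ellipse(cx - lat_off, cy - 0.05 * ny, lat_ax, lat_ay)
    lat_r2d = ellipse(cx + lat_off, cy - 0.05 * ny, lat_ax, lat_ay)
    third2d = ellipse(cx, cy + 0.06 * ny, 0.022 * nx * s, 0.09 * ny * s)
    fourth2d = ellipse(cx, cy + 0.26 * ny, 0.03 * nx * s, 0.05 * ny * s)

    zeros = lambda: np.zeros(grid_shape, dtype=bool)
    brain = zeros(); gm = zeros()
    lat_l = zeros(); lat_r = zeros(); third = zeros(); fourth = zeros()
    lat_slices = range(int(round(0.35 * nz)), max(int(round(0.35 * nz)) + 1, int(round(0.85 * nz))))
    third_slices = range(int(round(0.25 * nz)), max(int(round(0.25 * nz)) + 1, int(round(0.6 * nz))))
    fourth_slices = range(0, max(1, int(round(0.2 * nz))))
    for k in range(nz):
        brain[..., k] = brain2d
        gm[..., k] = gm2d
        if k in lat_slices:
            lat_l[..., k] = lat_l2d & interior2d
            lat_r[..., k] = lat_r2d & interior2d
        if k in third_slices:
            third[..., k] = third2d & interior2d
        if k in fourth_slices:
            fourth[..., k] = fourth2d & interior2d
    third &= ~(lat_l | lat_r)
    fourth &= ~(lat_l | lat_r | third)
    vents = lat_l | lat_r | third | fourth
    wm = brain & ~gm & ~vents
    return {
        "brain": brain, "wm": wm, "gm": gm, "csf": vents,
        "lat_l": lat_l, "lat_r": lat_r, "third": third, "fourth": fourth,
    }


def _sphere_bbox(grid_shape, voxel_size, center, radius_mm, pad_vox: int = 0):
    """Bounding-box slices and the local boolean sphere mask."""
    los, his = [], []
    for d in range(3):
        r_vox = radius_mm / voxel_size[d]
        los.append(max(0, int(math.floor(center[d] - r_vox)) - 1 - pad_vox))
        his.append(min(grid_shape[d], int(math.ceil(center[d] + r_vox)) + 2 + pad_vox))
    sl = tuple(slice(lo, hi) for lo, hi in zip(los, his))
    axes = [np.arange(lo, hi) for lo, hi in zip(los, his)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    r2 = (
        ((ii - center[0]) * voxel_size[0]) ** 2
        + ((jj - center[1]) * voxel_size[1]) ** 2
        + ((kk - center[2]) * voxel_size[2]) ** 2
    )
    return sl, r2 <= radius_mm**2


def _sphere_mask(grid_shape, voxel_size, center, radius_mm) -> np.ndarray:
    out = np.zeros(grid_shape, dtype=bool)
    sl, local = _sphere_bbox(grid_shape, voxel_size, center, radius_mm)
    out[sl] = local
    return out


def build_truth(spec: PhantomSpec, rng_field: np.random.Generator | None = None) -> PhantomTruth:
    """Construct geometry, labels, true parameter maps and fields.

    Cheap relative to signal generation; usable on its own when only
    ground-truth volumetrics are needed (e.g. cohort-level checks).
    """
    spec.validate_lesions()
    anatomy = _build_anatomy(spec.grid_shape, spec.voxel_size, spec.ventricle_scale)
    tp = spec.tissue_params
    shape = spec.grid_shape

    label = np.zeros(shape, dtype=np.int32)
    label[anatomy["wm"]] = 1
    label[anatomy["gm"]] = 2
    label[anatomy["csf"]] = 3

    type_vol = np.zeros(shape, dtype=np.int32)
    cbv = np.zeros(shape); fa = np.zeros(shape); md = np.full(shape, 1e-3)
    fiber = np.zeros(shape + (3,)); fiber[..., 0] = 1.0
    for name, code in (("wm", 1), ("gm", 2), ("csf", 3)):
        m = label == code
        cbv[m] = tp[name].cbv
        fa[m] = tp[name].fa
        md[m] = tp[name].md
        fiber[m] = tp[name].fiber

    vox_vol = float(np.prod(spec.voxel_size))
    core_masks: list[np.ndarray | None] = []
    for idx, les in enumerate(spec.lesion_specs):
        sphere = _sphere_mask(shape, spec.voxel_size, les.center, les.radius_mm)
        sphere &= anatomy["wm"] | (label >= 10)  # lesions live in WM; may abut others
        if les.true_type == "ring":
            core = _sphere_mask(
                shape, spec.voxel_size, les.center, les.radius_mm - les.ring_thickness_mm
            ) & sphere
            annulus = sphere & ~core
            type_vol[annulus] = TYPE_CODE["active"]
            type_vol[core] = TYPE_CODE[les.core_type]
            cbv[annulus] = les.lesion_cbv; fa[annulus] = les.lesion_fa
            cbv[core] = les.core_cbv; fa[core] = les.core_fa
            core_masks.append(core)
        else:
            type_vol[sphere] = TYPE_CODE[les.true_type]
            cbv[sphere] = les.lesion_cbv; fa[sphere] = les.lesion_fa
            core_masks.append(None)
        md[sphere] = les.md
        label[sphere] = 10 + idx

    # per-lesion truth from the *final* label volume, so later lesions that
    # overwrite earlier ones (overlapping actives) stay mutually consistent
    lesions: list[LesionTruth] = []
    for idx, les in enumerate(spec.lesion_specs):
        mine = label == 10 + idx
        n_vox = int(mine.sum())
        core = core_masks[idx]
        lesions.append(
            LesionTruth(
                lesion_id=idx, true_type=les.true_type, center=les.center,
                radius_mm=les.radius_mm, n_voxels=n_vox,
                volume_mm3=n_vox * vox_vol, cbv=les.lesion_cbv, fa=les.lesion_fa,
                core_type=les.core_type if les.true_type == "ring" else None,
                n_core_voxels=int((core & mine).sum()) if core is not None else 0,
                true_relation=getattr(les, "_relation", None),
            )
        )

    masks = TissueMasks(
        wm=(label == 1) | (label >= 10),  # lesions are (damaged) WM tissue
        gm=label == 2,
        csf=label == 3,
        lateral_left=anatomy["lat_l"],
        lateral_right=anatomy["lat_r"],
        third=anatomy["third"],
        fourth=anatomy["fourth"],
    )

    if spec.deformation_amplitude_mm > 0:
        rng = rng_field if rng_field is not None else spec._streams()["field"]
        fld = random_smooth_field(shape, spec.voxel_size, spec.deformation_amplitude_mm, rng)
    else:
        fld = DeformationField.identity(shape, spec.voxel_size)

    return PhantomTruth(
        label_volume=label, type_volume=type_vol, masks=masks, lesions=lesions,
        true_cbv=cbv, true_fa=fa, fiber=fiber, md=md, field=fld,
        voxel_size=spec.voxel_size,
    )


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------


def _add_noise(img: np.ndarray, sigma: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return img
    if model == "gaussian":
        return img + sigma * rng.standard_normal(img.shape)
    if model == "rician":
        # magnitude of a complex signal with iid Gaussian channel noise
        re = img + sigma * rng.standard_normal(img.shape)
        im = sigma * rng.standard_normal(img.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def _modality_image(spec: PhantomSpec, truth: PhantomTruth, modality: str) -> np.ndarray:
    tp = spec.tissue_params
    img = np.zeros(spec.grid_shape)
    label = truth.label_volume
    for name, code in (("wm", 1), ("gm", 2), ("csf", 3)):
        img[label == code] = getattr(tp[name], modality)[0]
    wm_mean = tp["wm"].__getattribute__(modality)[0]
    for idx, les in enumerate(spec.lesion_specs):
        m = label == 10 + idx
        if not m.any():
            continue
        if les.true_type == "ring":
            ann = m & (truth.type_volume == TYPE_CODE["active"])
            core = m & ~ann
            img[ann] = wm_mean + les.signal_offsets.get(modality, 0.0)
            img[core] = wm_mean + les.core_offsets.get(modality, 0.0)
        else:
            img[m] = wm_mean + les.signal_offsets.get(modality, 0.0)
    return img


def generate_structural(
    spec: PhantomSpec,
) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid, PhantomTruth]:
    """Generate co-registered FLAIR, T1-pre and T1-post volumes + truth.

    Noiseless phantoms satisfy the detection thresholds by construction:
    all lesion voxels exceed WM mean+2SD on FLAIR, hypointense lesion
    voxels fall below mean-2SD on T1-pre, active tissue exceeds
    mean+2SD on T1-post and its pre-contrast value.
    """
    streams = spec._streams()
    truth = build_truth(spec, rng_field=streams["field"])
    rng = streams["structural"]
    vols = []
    for modality in ("flair", "t1pre", "t1post"):
        img = _modality_image(spec, truth, modality)
        img = _add_noise(img, spec.noise_sigma, spec.noise_model, rng)
        vols.append(
            VolumeGrid(img, voxel_size=spec.voxel_size, units="signal")
        )
    return vols[0], vols[1], vols[2], truth


def gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Unit-integral gamma-variate bolus shape, zero before ``t0``."""
    tt = np.clip(t - t0, 0.0, None)
    norm = beta ** (alpha + 1.0) * math.gamma(alpha + 1.0)
    g = np.where(t > t0, tt**alpha * np.exp(-tt / beta), 0.0)
    return g / norm


# integrated Delta-R2* (s^-1 * s) contributed by one unit of relative CBV
K_CBV = 50.0
BOLUS_ALPHA = 3.0
BOLUS_BETA = 2.5  # s


def generate_dsc(
    spec: PhantomSpec,
    truth: PhantomTruth,
    n_timepoints: int = 60,
    tr: float = 1.9,
    te: float = 0.040,
    n_baseline: int = 10,
    k_cbv: float = K_CBV,
    alpha: float = BOLUS_ALPHA,
    beta: float = BOLUS_BETA,
) -> SeriesGrid:
    """Simulate the DSC bolus-passage series (TR/TE = 1.9 s / 40 ms).

    Each voxel's Delta-R2*(t) is a unit-integral gamma variate scaled by
    ``k_cbv * true_CBV``, so the time integral of Delta-R2* equals
    ``k_cbv * true_CBV`` exactly — relative CBV recovery is linear by
    construction.  Signal: S(t) = S0 * exp(-TE * Delta-R2*(t)).
    """
    if n_baseline < 8:
        raise ValueError("need a pre-bolus baseline of at least 8 frames")
    # first pass essentially complete by t0 + alpha*beta + 6*beta
    needed = n_baseline + int(np.ceil((alpha * beta + 6.0 * beta) / tr))
    if n_timepoints < needed:
        raise ValueError(
            f"n_timepoints={n_timepoints} too small to contain baseline + first pass "
            f"(need >= {needed})"
        )
    times = tr * np.arange(n_timepoints)
    t0 = tr * n_baseline
    g = gamma_variate(times, t0, alpha, beta)  # (nt,)
    dr2s = k_cbv * truth.true_cbv[..., None] * g[None, None, None, :]
    s0 = np.zeros(spec.grid_shape)
    label = truth.label_volume
    for name, code in (("wm", 1), ("gm", 2), ("csf", 3)):
        s0[label == code] = spec.tissue_params[name].dsc_s0
    s0[label >= 10] = LESION_DSC_S0
    data = s0[..., None] * np.exp(-te * dr2s)
    rng = spec._streams()["dsc"]
    data = _add_noise(data, spec.noise_sigma, spec.noise_model, rng)
    return SeriesGrid(
        data, voxel_size=spec.voxel_size, units="signal", frame_times=times
    )


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the hemisphere (Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = i / n  # hemisphere: z in (0, 1)
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def eigenvalues_from_fa_md(fa: np.ndarray, md: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axially symmetric eigenvalues (lambda1, lambda2=lambda3) with the
    requested FA and mean diffusivity.

    With r = lambda2/lambda1 the FA of a prolate tensor is
    ``(1 - r) / sqrt(1 + 2 r^2)``; solving for r gives the quadratic
    ``(2 FA^2 - 1) r^2 + 2 r + (FA^2 - 1) = 0`` whose root in (0, 1]
    is used.  Then lambda1 = 3 MD / (1 + 2 r).
    """
    fa = np.asarray(fa, dtype=float)
    md = np.asarray(md, dtype=float)
    a = 2.0 * fa**2 - 1.0
    c = fa**2 - 1.0
    disc = np.sqrt(np.clip(1.0 - a * c, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(np.abs(a) > 1e-12, (-1.0 + disc) / a, -c / 2.0)
    r = np.clip(r, 0.0, 1.0)
    lam1 = 3.0 * md / (1.0 + 2.0 * r)
    lam2 = r * lam1
    return lam1, lam2


def generate_dti(
    spec: PhantomSpec,
    truth: PhantomTruth,
    bvecs: np.ndarray | None = None,
    bval: float = 1500.0,
    n_b0: int = 6,
) -> SeriesGrid:
    """Simulate the diffusion series: 6 b=0 frames + 55 directions at
    b = 1500 s/mm^2 (protocol defaults), monoexponential tensor signal.
    """
    if bvecs is None:
        bvecs = fibonacci_directions(55)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise ValueError("bvecs must be (n, 3)")
    norms = np.linalg.norm(bvecs, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("gradient directions must be unit norm")
    if bvecs.shape[0] < 6:
        raise ValueError("at least 6 gradient directions are required")

    lam1, lam2 = eigenvalues_from_fa_md(truth.true_fa, truth.md)
    s0 = np.zeros(spec.grid_shape)
    label = truth.label_volume
    for name, code in (("wm", 1), ("gm", 2), ("csf", 3)):
        s0[label == code] = spec.tissue_params[name].dti_s0
    s0[label >= 10] = LESION_DTI_S0

    n_dir = bvecs.shape[0]
    n_frames = n_b0 + n_dir
    data = np.empty(spec.grid_shape + (n_frames,))
    data[..., :n_b0] = s0[..., None]
    # g^T D g = lam2 + (lam1 - lam2) * (g . e1)^2 for axially symmetric D
    dot = np.einsum("xyzc,nc->xyzn", truth.fiber, bvecs)
    adc = lam2[..., None] + (lam1 - lam2)[..., None] * dot**2
    data[..., n_b0:] = s0[..., None] * np.exp(-bval * adc)

    rng = spec._streams()["dti"]
    data = _add_noise(data, spec.noise_sigma, spec.noise_model, rng)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dir, bval)])
    all_vecs = np.concatenate([np.zeros((n_b0, 3)), bvecs])
    return SeriesGrid(
        data, voxel_size=spec.voxel_size, units="signal", bvals=bvals, bvecs=all_vecs
    )


def apply_synthetic_distortion(series: SeriesGrid, fld: DeformationField) -> SeriesGrid:
    """Warp a clean (structural-space) series into distorted EPI space.

    Uses the field's target->source member so the paired forward
    (source->target) mapping is exactly the correction a registration
    step should recover.  An identity field returns the input unchanged.
    """
    if series.shape[:3] != fld.shape:
        raise ValueError("series and field grids do not match")
    fld.check_invertible()
    if not fld.inverse.any():
        return series.with_data(series.data.copy())
    out = np.empty_like(series.data)
    from .fields import warp_volume

    for t in range(series.n_frames):
        out[..., t] = warp_volume(series.data[..., t], fld.inverse, series.voxel_size)
    return series.with_data(out)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class EffectConfig:
    """Latent correlation structure and effect sizes for a cohort.

    Defaults mirror the study conditions: lesion load (T1-hypointense +
    active volume) correlates with ventricular volume at 0.85, ventricle
    volume with EDSS at 0.80, patients' ventricles are enlarged versus
    controls, and lesion CBV/FA effects follow the reported directions
    (hypointense: CBV and FA reduced; active: FA reduced, CBV elevated;
    isointense: near-normal).  Latent subject variables map linearly
    onto targets so Pearson correlations survive the mapping.
    """

    r_lesion_ventricle: float = 0.85
    r_ventricle_edss: float = 0.80
    r_lesion_edss: float = 0.68  # ~ product of the two above; keeps matrix PSD
    lesion_load_mean_mm3: float = 3500.0
    lesion_load_sd_mm3: float = 1400.0
    lesion_load_min_mm3: float = 600.0
    patient_ventricle_mean_mm3: float = 10000.0
    patient_ventricle_sd_mm3: float = 2800.0
    control_ventricle_mean_mm3: float = 6000.0
    control_ventricle_sd_mm3: float = 1000.0
    ventricle_min_mm3: float = 3000.0
    edss_mean: float = 4.0
    edss_sd: float = 1.8
    lesion_radius_range_mm: tuple[float, float] = (2.5, 5.0)
    iso_per_load_lesion: float = 1.1  # isointense lesions per load-bearing lesion
    p_ring_given_active: float = 0.2
    relation_probs: tuple[float, float, float] = (0.56, 0.40, 0.04)  # adjacent/overlap/independent
    active_load_fraction: float = 0.2
    # per-subject heterogeneity of lesion severity: scales each lesion's
    # CBV/FA *deviation from normal WM*, so lesion types whose true values
    # equal WM stay exactly null
    effect_subject_rel_sd: float = 0.15
    # biological between-subject variation of normal WM itself (applied
    # coherently to lesion values, preserving the deviations)
    wm_fa_subject_sd: float = 0.012
    wm_cbv_subject_rel_sd: float = 0.04
    noise_sigma: float = 5.0  # SNR ~ 20 at the WM signal level
    deformation_amplitude_mm: float = 0.0
    grid_shape: tuple[int, int, int] = (80, 80, 10)
    voxel_size: tuple[float, float, float] = (0.9375, 0.9375, 4.0)

    def correlation_matrix(self) -> np.ndarray:
        m = np.array(
            [
                [1.0, self.r_lesion_ventricle, self.r_lesion_edss],
                [self.r_lesion_ventricle, 1.0, self.r_ventricle_edss],
                [self.r_lesion_edss, self.r_ventricle_edss, 1.0],
            ]
        )
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("requested correlation matrix is not positive semi-definite")
        return m


@dataclass
class SubjectRecord:
    subject_id: str
    group: Literal["patient", "control"]
    spec: PhantomSpec
    edss: float | None
    latent: dict[str, float] = field(default_factory=dict)


def _base_ventricle_volume(grid_shape, voxel_size) -> float:
    anat = _build_anatomy(grid_shape, voxel_size, 1.0)
    n = int((anat["lat_l"] | anat["lat_r"] | anat["third"] | anat["fourth"]).sum())
    return n * float(np.prod(voxel_size))


def place_lesions(
    anatomy: dict[str, np.ndarray],
    voxel_size,
    rng: np.random.Generator,
    load_target_mm3: float,
    cfg: EffectConfig,
) -> list[LesionSpec]:
    """Place spherical lesions in WM until the hypo+active volume target
    is reached, enforcing CSF clearance and controlled spatial relations
    between active and hypointense lesions.
    """
    wm = anatomy["wm"]
    csf = anatomy["csf"]
    shape = wm.shape
    vox_vol = float(np.prod(voxel_size))
    # clearance map: distance (mm) to anything that is not plain WM; the
    # CSF margin matches the downstream exclusion rule (8-connected
    # in-plane dilation) plus one voxel of safety
    struct8 = ndimage.generate_binary_structure(2, 2)
    csf_near = np.stack(
        [ndimage.binary_dilation(csf[..., k], struct8, iterations=3)
         for k in range(csf.shape[2])], axis=2,
    )
    free = wm & ~csf_near
    dist = ndimage.distance_transform_edt(free, sampling=voxel_size)
    # occupancy, pre-dilated by 2 voxels so a simple intersection test
    # enforces the inter-lesion gap
    occupied_near = np.zeros(shape, dtype=bool)

    def mark_occupied(center, radius_mm):
        sl, local = _sphere_bbox(shape, voxel_size, center, radius_mm, pad_vox=2)
        occupied_near[sl] |= ndimage.binary_dilation(local, iterations=2)

    def wm_volume_at(center, radius_mm):
        sl, local = _sphere_bbox(shape, voxel_size, center, radius_mm)
        return float((local & wm[sl]).sum()) * vox_vol

    def local_sphere(sl, center, radius_mm):
        axes = [np.arange(s.start, s.stop) for s in sl]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        r2 = (
            ((ii - center[0]) * voxel_size[0]) ** 2
            + ((jj - center[1]) * voxel_size[1]) ** 2
            + ((kk - center[2]) * voxel_size[2]) ** 2
        )
        return r2 <= radius_mm**2

    def try_place(radius_mm, near=None, overlap_with=None, far_from=None, tries=60):
        free_idx = None
        for _ in range(tries):
            if overlap_with is not None:
                c0 = np.asarray(overlap_with.center, dtype=float)
                jitter = rng.uniform(-1.0, 1.0, size=2) * 0.3 * overlap_with.radius_mm
                cand = (c0[0] + jitter[0] / voxel_size[0], c0[1] + jitter[1] / voxel_size[1], c0[2])
            elif near is not None:
                c0 = np.asarray(near.center, dtype=float)
                theta = rng.uniform(0, 2 * math.pi)
                d_mm = near.radius_mm + radius_mm + 1.0  # 1 mm surface gap
                cand = (
                    c0[0] + d_mm * math.cos(theta) / voxel_size[0],
                    c0[1] + d_mm * math.sin(theta) / voxel_size[1],
                    c0[2],
                )
            else:
                if free_idx is None:
                    free_idx = np.argwhere(dist >= radius_mm + 0.5)
                    if free_idx.size == 0:
                        return None
                i = rng.integers(len(free_idx))
                cand = tuple(float(v) for v in free_idx[i])
            ci = tuple(int(round(v)) for v in cand)
            if not all(0 <= ci[d] < shape[d] for d in range(3)):
                continue
            if dist[ci] < radius_mm + 0.5:
                continue
            if overlap_with is None:
                sl, local = _sphere_bbox(shape, voxel_size, cand, radius_mm)
                clash = local & occupied_near[sl]
                if near is not None:
                    clash &= ~local_sphere(sl, near.center, near.radius_mm + 2.5 * voxel_size[0])
                if clash.any():
                    continue
            if far_from is not None and far_from:
                ok = True
                for other in far_from:
                    d = np.linalg.norm(
                        (np.asarray(cand) - np.asarray(other.center)) * np.asarray(voxel_size)
                    )
                    if d < other.radius_mm + radius_mm + 8.0:
                        ok = False
                        break
                if not ok:
                    continue
            return cand
        return None

    lesions: list[LesionSpec] = []
    hypo_lesions: list[LesionSpec] = []
    rmin, rmax = cfg.lesion_radius_range_mm

    # pass 1: hypointense lesions carry most of the load
    hypo_target = (1.0 - cfg.active_load_fraction) * load_target_mm3
    acc = 0.0
    while acc < hypo_target and len(lesions) < 120:
        r = rng.uniform(rmin, rmax)
        placed = try_place(r)
        if placed is None:
            r = rmin  # saturating: fall back to the smallest lesion size
            placed = try_place(r)
        if placed is None:
            break
        cand = placed
        les = LesionSpec(center=cand, radius_mm=r, true_type="t1_hypointense")
        lesions.append(les)
        hypo_lesions.append(les)
        mark_occupied(cand, r)
        acc += wm_volume_at(cand, r)

    # pass 2: active / ring lesions with controlled spatial relations
    active_target = cfg.active_load_fraction * load_target_mm3
    acc_a = 0.0
    rel_labels = ("adjacent", "overlapping", "independent")
    attempts = 60
    while acc_a < active_target and len(lesions) < 160 and attempts > 0:
        attempts -= 1
        r = rng.uniform(rmin, min(rmax, 4.5))
        rel = rel_labels[rng.choice(3, p=np.asarray(cfg.relation_probs))]
        if rel == "adjacent" and rng.uniform() < cfg.p_ring_given_active:
            # a ring's enhancing annulus surrounds its own hypointense
            # core: the canonical "adjacent/surrounding" configuration
            r = max(r, 3.4)
            placed = try_place(r)
            if placed is None:
                continue
            cand = placed
            les = LesionSpec(
                center=cand, radius_mm=r,
                true_type="ring", ring_thickness_mm=min(1.5, 0.45 * r),
            )
            les._relation = "adjacent"
        else:
            placed = None
            if rel == "overlapping" and hypo_lesions:
                for host in rng.permutation(len(hypo_lesions))[:5]:
                    host = hypo_lesions[host]
                    r_o = min(r, 0.7 * host.radius_mm)
                    placed = try_place(r_o, overlap_with=host)
                    if placed is not None:
                        r = r_o
                        break
                if placed is None:
                    continue
                cand = placed
                les = LesionSpec(
                    center=cand, radius_mm=r, true_type="active",
                    signal_offsets={"flair": 25.0, "t1pre": -25.0, "t1post": 30.0},
                )
            elif rel == "adjacent" and hypo_lesions:
                for host in rng.permutation(len(hypo_lesions))[:5]:
                    placed = try_place(r, near=hypo_lesions[host])
                    if placed is not None:
                        break
                if placed is None:
                    continue
                cand = placed
                les = LesionSpec(center=cand, radius_mm=r, true_type="active")
            else:
                rel = "independent"
                placed = try_place(r, far_from=hypo_lesions)
                if placed is None:
                    continue
                cand = placed
                les = LesionSpec(center=cand, radius_mm=r, true_type="active")
            les._relation = rel
        lesions.append(les)
        mark_occupied(cand, r)
        acc_a += wm_volume_at(cand, r)

    # pass 3: isointense lesions in proportion
    n_iso = int(round(cfg.iso_per_load_lesion * len(lesions)))
    placed_iso, attempts = 0, 4 * n_iso
    while placed_iso < n_iso and attempts > 0:
        attempts -= 1
        r = rng.uniform(rmin, rmax)
        placed = try_place(r)
        if placed is None:
            continue
        cand = placed
        lesions.append(LesionSpec(center=cand, radius_mm=r, true_type="t1_isointense"))
        mark_occupied(cand, r)
        placed_iso += 1
    return lesions


def _subject_tissue_params(
    cfg: EffectConfig, rng: np.random.Generator
) -> tuple[dict[str, TissueParams], float, float]:
    """Tissue parameters with this subject's normal-WM baseline drawn."""
    tissue = default_tissue_params()
    wm = tissue["wm"]
    wm_fa = float(np.clip(wm.fa + cfg.wm_fa_subject_sd * rng.standard_normal(), 0.05, 0.9))
    wm_cbv = float(max(0.2, wm.cbv * (1.0 + cfg.wm_cbv_subject_rel_sd * rng.standard_normal())))
    tissue["wm"] = replace(wm, fa=wm_fa, cbv=wm_cbv)
    return tissue, wm_fa, wm_cbv


def generate_cohort(
    n_patients: int = 7,
    n_controls: int = 7,
    effect_config: EffectConfig | None = None,
    rng_seed: int = 0,
) -> list[SubjectRecord]:
    """Draw a synthetic cohort with controlled correlation structure.

    Latent per-subject variables (lesion load, ventricle volume, EDSS)
    are multivariate normal with the configured pairwise correlations
    and map linearly (with mild clipping and half-point EDSS rounding)
    onto the generative targets, so downstream Pearson recovery is
    testable.  Controls carry no lesions.  Image data are not realized
    here — each subject's :class:`PhantomSpec` regenerates them
    deterministically on demand.
    """
    cfg = effect_config or EffectConfig()
    corr = cfg.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    rng = np.random.default_rng(rng_seed)
    base_vent = _base_ventricle_volume(cfg.grid_shape, cfg.voxel_size)

    subjects: list[SubjectRecord] = []
    patient_tissue: list[dict[str, TissueParams]] = []
    for p in range(n_patients):
        z = chol @ rng.standard_normal(3)
        load = max(cfg.lesion_load_min_mm3,
                   cfg.lesion_load_mean_mm3 + cfg.lesion_load_sd_mm3 * z[0])
        vent = max(cfg.ventricle_min_mm3,
                   cfg.patient_ventricle_mean_mm3 + cfg.patient_ventricle_sd_mm3 * z[1])
        edss = float(np.clip(round(2.0 * (cfg.edss_mean + cfg.edss_sd * z[2])) / 2.0, 0.0, 10.0))
        vscale = math.sqrt(vent / base_vent)  # in-plane scaling: volume ~ scale^2
        seed = int(rng.integers(2**31 - 1))
        anatomy = _build_anatomy(cfg.grid_shape, cfg.voxel_size, vscale)
        lesions = place_lesions(anatomy, cfg.voxel_size, np.random.default_rng(seed), load, cfg)
        # per-subject heterogeneity: normal-WM baseline variation plus a
        # scaling of each lesion's deviation from that baseline
        tissue, wm_fa, wm_cbv = _subject_tissue_params(cfg, rng)
        patient_tissue.append(tissue)
        z_cbv, z_fa = rng.standard_normal(2)
        s_cbv = 1.0 + cfg.effect_subject_rel_sd * z_cbv
        s_fa = 1.0 + cfg.effect_subject_rel_sd * z_fa

        def _apply(base_cbv, base_fa):
            cbv = wm_cbv * (1.0 + (base_cbv - 1.0) * s_cbv)
            fa = wm_fa + (base_fa - 0.45) * s_fa
            return float(np.clip(cbv, 0.02, 3.0)), float(np.clip(fa, 0.0, 0.95))

        for les in lesions:
            les.lesion_cbv, les.lesion_fa = _apply(les.lesion_cbv, les.lesion_fa)
            if les.true_type == "ring":
                les.core_cbv, les.core_fa = _apply(les.core_cbv, les.core_fa)
        spec = PhantomSpec(
            grid_shape=cfg.grid_shape, voxel_size=cfg.voxel_size,
            tissue_params=tissue,
            lesion_specs=lesions, noise_sigma=cfg.noise_sigma,
            deformation_amplitude_mm=cfg.deformation_amplitude_mm,
            rng_seed=seed, ventricle_scale=vscale,
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"patient_{p:03d}", group="patient", spec=spec, edss=edss,
                latent={"lesion_load_mm3": load, "ventricle_mm3": vent, "edss": edss},
            )
        )
    for c in range(n_controls):
        vent = max(cfg.ventricle_min_mm3,
                   cfg.control_ventricle_mean_mm3
                   + cfg.control_ventricle_sd_mm3 * rng.standard_normal())
        vscale = math.sqrt(vent / base_vent)
        seed = int(rng.integers(2**31 - 1))
        # controls are matched to patients: a matched pair shares its
        # normal-WM baseline, mirroring the age/gender matching of the
        # study design and removing chance group baseline differences
        if c < len(patient_tissue):
            tissue = {k: replace(v) for k, v in patient_tissue[c].items()}
        else:
            tissue, _, _ = _subject_tissue_params(cfg, rng)
        spec = PhantomSpec(
            grid_shape=cfg.grid_shape, voxel_size=cfg.voxel_size,
            tissue_params=tissue,
            lesion_specs=[], noise_sigma=cfg.noise_sigma,
            deformation_amplitude_mm=cfg.deformation_amplitude_mm,
            rng_seed=seed, ventricle_scale=vscale,
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"control_{c:03d}", group="control", spec=spec, edss=None,
                latent={"ventricle_mm3": vent},
            )
        )
    return subjects


def cohort_truth_table(subjects: Sequence[SubjectRecord]):
    """Ground-truth volumetrics per subject (no signal realization).

    Returns a pandas DataFrame with measured (voxelized) lesion load,
    ventricle volumes and EDSS — the substrate for correlation checks
    on the generator itself.
    """
    import pandas as pd

    rows = []
    for s in subjects:
        truth = build_truth(s.spec)
        vox_vol = float(np.prod(s.spec.voxel_size))
        load_types = (TYPE_CODE["active"], TYPE_CODE["t1_hypointense"])
        load = float(np.isin(truth.type_volume, load_types).sum()) * vox_vol
        masks = truth.masks
        lat = (masks.lateral_left.sum() + masks.lateral_right.sum()) * vox_vol
        total = lat + (masks.third.sum() + masks.fourth.sum()) * vox_vol
        rows.append(
            {
                "subject": s.subject_id, "group": s.group,
                "lesion_load_mm3": load, "lateral_ventricle_mm3": float(lat),
                "total_ventricle_mm3": float(total), "edss": s.edss,
                "n_lesions": len(truth.lesions),
            }
        )
    return pd.DataFrame(rows)
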