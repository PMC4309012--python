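"""Parametric maps from perfusion and diffusion series.

Relative CBV follows the first-pass integration approach: the contrast
bolus transiently raises the transverse relaxation rate,
``Delta-R2*(t) = -ln(S(t)/S0) / TE``, and the time integral of
Delta-R2* over the first pass is proportional to the blood volume of
the voxel.  No arterial input function is used, so the maps are in
relative units (optionally normalized to a reference-WM mean).

FA comes from the diffusion tensor: a log-linear least-squares fit of
``ln S = ln S0 - b g^T D g`` over the gradient scheme, eigendecomposed
per voxel, with

    FA = sqrt(3/2) * sqrt(sum_i (lambda_i - lambda_mean)^2)
                   / sqrt(sum_i lambda_i^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .grids import SeriesGrid, VolumeGrid

__all__ = [
    "TensorField",
    "compute_delta_r2star",
    "compute_cbv",
    "detect_bolus_arrival",
    "fit_dti",
    "compute_fa",
    "fa_from_eigenvalues",
]


# ---------------------------------------------------------------------------
# DSC / CBV
# ---------------------------------------------------------------------------


def compute_delta_r2star(
    dsc: SeriesGrid, baseline_frames: slice | tuple[int, int], te: float
) -> SeriesGrid:
    """Convert a DSC signal series to a Delta-R2* time series.

    ``S0`` is the mean over the pre-bolus baseline frames.  Voxels with
    non-positive baseline, and frames with non-positive signal, are
    marked NaN instead of producing infinities.
    """
    if te <= 0:
        raise ValueError("TE must be positive")
    if isinstance(baseline_frames, tuple):
        baseline_frames = slice(*baseline_frames)
    n = dsc.n_frames
    idx = range(*baseline_frames.indices(n))
    if len(idx) == 0:
        raise ValueError("baseline frame range is empty or out of bounds")
    s0 = dsc.data[..., baseline_frames].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = dsc.data / s0[..., None]
        dr2s = np.where((s0[..., None] > 0) & (dsc.data > 0), -np.log(ratio) / te, np.nan)
    return SeriesGrid(
        dr2s, voxel_size=dsc.voxel_size, origin=dsc.origin,
        units="1/s", frame_times=dsc.frame_times,
    )


def detect_bolus_arrival(
    dsc: SeriesGrid, baseline_frames: slice, brain_mask: np.ndarray, k: float = 3.0
) -> int:
    """First frame where the mean brain signal drops more than
    ``k`` baseline SDs below the baseline mean (automatic bolus onset).
    """
    mean_ts = dsc.data[brain_mask].mean(axis=0)
    base = mean_ts[baseline_frames]
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    below = np.nonzero(mean_ts < mu - k * sd)[0]
    stop = range(*baseline_frames.indices(dsc.n_frames))[-1]
    below = below[below > stop]
    if below.size == 0:
        raise ValueError("no bolus transit detected in the series")
    return int(below[0])


def _gamma_model(t, a, t0, alpha, beta):
    tt = np.clip(t - t0, 0, None)
    return np.where(t > t0, a * tt**alpha * np.exp(-tt / beta), 0.0)


def compute_cbv(
    delta_r2star: SeriesGrid,
    integration_window: slice | tuple[int, int],
    mode: str = "trapezoid",
    fit_mask: np.ndarray | None = None,
) -> VolumeGrid:
    """Integrate Delta-R2* over the first pass into a relative-CBV map.

    ``mode="trapezoid"`` (default) integrates the measured curve over
    the window.  ``mode="gamma"`` fits a gamma variate per voxel and
    integrates the fit analytically, which excludes recirculation; it
    loops ``scipy.curve_fit`` per voxel and is intended for ROI-sized
    regions (restrict with ``fit_mask``).
    """
    if isinstance(integration_window, tuple):
        integration_window = slice(*integration_window)
    n = delta_r2star.n_frames
    win = range(*integration_window.indices(n))
    if len(win) < 3:
        raise ValueError("integration window must span at least 3 frames")
    times = delta_r2star.frame_times
    if times is None:
        raise ValueError("Delta-R2* series carries no frame times")
    tw = times[integration_window]
    curves = delta_r2star.data[..., integration_window]

    if mode == "trapezoid":
        cbv = np.trapezoid(curves, tw, axis=-1)
        cbv = np.where(np.isnan(curves).any(axis=-1), np.nan, cbv)
    elif mode == "gamma":
        import math

        shape = delta_r2star.shape[:3]
        cbv = np.full(shape, np.nan)
        voxels = np.argwhere(fit_mask) if fit_mask is not None else np.argwhere(
            np.ones(shape, dtype=bool)
        )
        for i, j, k in voxels:
            y = curves[i, j, k]
            if np.isnan(y).any():
                continue
            peak = float(y.max())
            if peak <= 0:
                cbv[i, j, k] = 0.0
                continue
            t_pk = float(tw[int(np.argmax(y))])
            try:
                p0 = (peak, max(tw[0], t_pk - 7.0), 3.0, 2.5)
                popt, _ = curve_fit(
                    _gamma_model, tw, y, p0=p0, maxfev=5000,
                    bounds=([0, tw[0] - 20, 0.5, 0.2], [np.inf, t_pk, 10, 20]),
                )
                a, t0, alpha, beta = popt
                cbv[i, j, k] = a * beta ** (alpha + 1.0) * math.gamma(alpha + 1.0)
            except RuntimeError:
                cbv[i, j, k] = np.trapezoid(y, tw)
    else:
        raise ValueError(f"unknown CBV mode {mode!r}")
    return VolumeGrid(
        cbv, voxel_size=delta_r2star.voxel_size, origin=delta_r2star.origin,
        units="relative units",
    )


# ---------------------------------------------------------------------------
# DTI / FA
# ---------------------------------------------------------------------------


@dataclass
class TensorField:
    """Per-voxel diffusion tensor fit results.

    ``tensor`` holds the symmetric D (mm^2/s) per voxel; eigenvalues
    are sorted descending.  ``valid`` is False where the fit failed
    (non-positive signals / degenerate data); ``clamped`` marks voxels
    whose negative eigenvalues were floored.
    """

    tensor: np.ndarray  # (nx, ny, nz, 3, 3)
    s0: np.ndarray
    eigenvalues: np.ndarray  # (nx, ny, nz, 3), descending
    eigenvectors: np.ndarray  # (nx, ny, nz, 3, 3), columns match eigenvalues
    valid: np.ndarray
    clamped: np.ndarray
    voxel_size: tuple[float, float, float]
    design_condition: float

    @property
    def clamped_fraction(self) -> float:
        n_valid = int(self.valid.sum())
        return float(self.clamped.sum()) / n_valid if n_valid else 0.0


_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    b = bvals
    cols = [
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ]
    return np.stack(cols, axis=1)


def fit_dti(dwi: SeriesGrid, eig_floor: float = 1e-12) -> TensorField:
    """Log-linear least-squares tensor fit of a diffusion series.

    Requires at least one b=0 frame and six non-collinear directions.
    Negative eigenvalues are clamped to a small positive floor and the
    voxel flagged rather than discarded, so ROI statistics remain
    computable; the flagged fraction is available on the result.
    """
    if dwi.bvals is None or dwi.bvecs is None:
        raise ValueError("series carries no diffusion encoding")
    weighted = dwi.bvals > 0
    if (~weighted).sum() < 1:
        raise ValueError("at least one b=0 frame is required")
    if weighted.sum() < 6:
        raise ValueError("at least 6 diffusion-weighted directions are required")
    design = _design_matrix(dwi.bvals, dwi.bvecs)
    cond = float(np.linalg.cond(design))
    if cond > 1e8:
        raise ValueError("degenerate (collinear) gradient set; tensor unidentifiable")

    shape = dwi.shape[:3]
    flat = dwi.data.reshape(-1, dwi.n_frames)
    valid = (flat > 0).all(axis=1)
    log_s = np.zeros_like(flat)
    log_s[valid] = np.log(flat[valid])
    coef = np.linalg.lstsq(design, log_s[valid].T, rcond=None)[0]  # (7, n_valid)

    s0 = np.full(flat.shape[0], np.nan)
    s0[valid] = np.exp(coef[0])
    tensor = np.full((flat.shape[0], 3, 3), np.nan)
    t = np.zeros((valid.sum(), 3, 3))
    for c, (i, j) in enumerate(_TENSOR_IDX, start=1):
        t[:, i, j] = coef[c]
        t[:, j, i] = coef[c]
    tensor[valid] = t

    evals = np.full((flat.shape[0], 3), np.nan)
    evecs = np.full((flat.shape[0], 3, 3), np.nan)
    w, v = np.linalg.eigh(t)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    clamped_v = (w < 0).any(axis=1)
    w = np.clip(w, eig_floor, None)
    evals[valid] = w
    evecs[valid] = v
    clamped = np.zeros(flat.shape[0], dtype=bool)
    clamped[valid] = clamped_v

    return TensorField(
        tensor=tensor.reshape(shape + (3, 3)),
        s0=s0.reshape(shape),
        eigenvalues=evals.reshape(shape + (3,)),
        eigenvectors=evecs.reshape(shape + (3, 3)),
        valid=valid.reshape(shape),
        clamped=clamped.reshape(shape),
        voxel_size=dwi.voxel_size,
        design_condition=cond,
    )


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues (last axis length 3)."""
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa(tensors: TensorField) -> VolumeGrid:
    """FA map from a fitted tensor field; invalid voxels propagate NaN."""
    fa = fa_from_eigenvalues(tensors.eigenvalues)
    fa = np.where(tensors.valid, fa, np.nan)
    return VolumeGrid(fa, voxel_size=tensors.voxel_size, units="dimensionless")
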