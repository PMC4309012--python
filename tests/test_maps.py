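"""Parametric-map estimators: Delta-R2*/CBV and tensor/FA."""

import numpy as np
import pytest

from mslesion import phantom
from mslesion.grids import SeriesGrid
from mslesion.maps import (
    compute_cbv,
    compute_delta_r2star,
    compute_fa,
    detect_bolus_arrival,
    fa_from_eigenvalues,
    fit_dti,
)

VOX = (0.9375, 0.9375, 4.0)


def _series(data, times=None, **kw):
    return SeriesGrid(np.asarray(data, float), voxel_size=VOX, frame_times=times, **kw)


# ------------------------------------------------------------------ Delta-R2*


def test_flat_signal_gives_zero_dr2star():
    data = np.full((2, 2, 1, 20), 100.0)
    dr2s = compute_delta_r2star(_series(data, np.arange(20.0)), slice(0, 8), te=0.04)
    assert np.allclose(dr2s.data, 0.0)


def test_dr2star_inverts_exponential_definition():
    k = 7.3
    te = 0.04
    data = np.full((1, 1, 1, 12), 100.0)
    data[..., 9] = 100.0 * np.exp(-te * k)
    dr2s = compute_delta_r2star(_series(data, np.arange(12.0)), slice(0, 8), te)
    assert dr2s.data[0, 0, 0, 9] == pytest.approx(k, rel=1e-12)


def test_nonpositive_signals_marked_invalid_not_infinite():
    data = np.full((1, 2, 1, 10), 100.0)
    data[0, 0, 0, 5] = -1.0  # transient dropout
    data[0, 1, 0, :] = 0.0  # dead voxel: S0 <= 0
    dr2s = compute_delta_r2star(_series(data, np.arange(10.0)), slice(0, 4), te=0.04)
    assert np.isnan(dr2s.data[0, 0, 0, 5]) and np.isfinite(dr2s.data[0, 0, 0, 6])
    assert np.isnan(dr2s.data[0, 1, 0]).all()
    with pytest.raises(ValueError, match="baseline"):
        compute_delta_r2star(_series(data, np.arange(10.0)), slice(5, 5), te=0.04)


# ----------------------------------------------------------------------- CBV


def test_cbv_zero_integrand_and_window_validation():
    dr2s = _series(np.zeros((2, 2, 1, 20)), np.arange(20.0))
    cbv = compute_cbv(dr2s, slice(5, 20))
    assert np.allclose(cbv.data, 0.0)
    assert cbv.units == "relative units"
    with pytest.raises(ValueError, match="3 frames"):
        compute_cbv(dr2s, slice(5, 7))


def test_cbv_recovers_true_ratio_on_phantom(four_type_spec, four_type_study):
    """Noiseless generator -> Delta-R2* -> trapezoid integral preserves
    true CBV ratios to better than 1%."""
    truth = four_type_study[3]
    dsc = phantom.generate_dsc(four_type_spec, truth)
    dr2s = compute_delta_r2star(dsc, slice(0, 10), te=0.040)
    cbv = compute_cbv(dr2s, slice(10, dsc.n_frames))
    hypo = truth.type_volume == 2
    wm = truth.label_volume == 1
    measured = cbv.data[hypo].mean() / cbv.data[wm].mean()
    assert measured == pytest.approx(0.4, rel=0.01)  # hypointense CBV 0.4 vs WM 1.0


def test_gamma_fit_mode_matches_trapezoid_on_clean_curve(four_type_spec, four_type_study):
    truth = four_type_study[3]
    dsc = phantom.generate_dsc(four_type_spec, truth)
    dr2s = compute_delta_r2star(dsc, slice(0, 10), te=0.040)
    win = slice(10, dsc.n_frames)
    mask = np.zeros(four_type_spec.grid_shape, bool)
    wm_idx = np.argwhere(truth.label_volume == 1)[:40]
    mask[tuple(wm_idx.T)] = True
    trap = compute_cbv(dr2s, win)
    gam = compute_cbv(dr2s, win, mode="gamma", fit_mask=mask)
    ratio = gam.data[mask] / trap.data[mask]
    assert np.abs(ratio - 1.0).max() < 0.02


def test_bolus_arrival_detection(four_type_spec, four_type_study):
    truth = four_type_study[3]
    spec = phantom.PhantomSpec(**{**four_type_spec.__dict__, "noise_sigma": 1.0})
    dsc = phantom.generate_dsc(spec, truth, n_baseline=10)
    onset = detect_bolus_arrival(dsc, slice(0, 10), truth.brain_mask)
    assert 10 <= onset <= 14  # bolus injected at frame 10


# ----------------------------------------------------------------------- DTI


def test_fit_recovers_generated_tensor_exactly(four_type_spec, four_type_study):
    truth = four_type_study[3]
    dti = phantom.generate_dti(four_type_spec, truth)
    tf = fit_dti(dti)
    # condition number is reported; scale mismatch between the ln-S0
    # column and the b-weighted columns puts it in the thousands
    assert np.isfinite(tf.design_condition) and tf.design_condition < 1e5
    lam1, lam2 = phantom.eigenvalues_from_fa_md(truth.true_fa, truth.md)
    wm = truth.label_volume == 1
    assert np.allclose(tf.eigenvalues[wm][:, 0], lam1[wm], rtol=1e-6)
    assert np.allclose(tf.eigenvalues[wm][:, 1], lam2[wm], rtol=1e-6)
    fa = compute_fa(tf)
    assert np.abs(fa.data[wm] - truth.true_fa[wm]).max() < 1e-6


def test_fit_requires_identifiable_design(four_type_spec, four_type_study):
    truth = four_type_study[3]
    collinear = np.tile([1.0, 0.0, 0.0], (10, 1))
    with pytest.raises(ValueError, match="degenerate|collinear"):
        dti = phantom.generate_dti(four_type_spec, truth, bvecs=collinear)
        fit_dti(dti)


def test_fa_closed_forms():
    assert fa_from_eigenvalues(np.array([2e-3, 2e-3, 2e-3])) == pytest.approx(0.0, abs=1e-12)
    assert fa_from_eigenvalues(np.array([2e-3, 0.0, 0.0])) == pytest.approx(1.0, abs=1e-12)
    assert fa_from_eigenvalues(np.array([2e-3, 1e-3, 1e-3])) == pytest.approx(
        1.0 / np.sqrt(6.0), abs=1e-12
    )


def test_fa_bounded_under_noise():
    """FA stays in [0, 1] on every valid voxel regardless of noise."""
    spec = phantom.PhantomSpec(grid_shape=(32, 32, 4), voxel_size=VOX,
                               noise_sigma=10.0, rng_seed=4)
    truth = phantom.build_truth(spec)
    dti = phantom.generate_dti(spec, truth)
    tf = fit_dti(dti)
    fa = compute_fa(tf).data
    valid = tf.valid & np.isfinite(fa)
    assert ((fa[valid] >= 0) & (fa[valid] <= 1)).all()


def test_cbv_invariant_under_signal_scaling(four_type_spec, four_type_study):
    truth = four_type_study[3]
    dsc = phantom.generate_dsc(four_type_spec, truth)
    scaled = dsc.with_data(3.7 * dsc.data)
    a = compute_cbv(compute_delta_r2star(dsc, slice(0, 10), 0.04), slice(10, 60))
    b = compute_cbv(compute_delta_r2star(scaled, slice(0, 10), 0.04), slice(10, 60))
    assert np.allclose(a.data, b.data, atol=1e-9, equal_nan=True)


def test_fa_invariant_under_joint_rotation(four_type_spec):
    """Rotating the gradient set together with the fiber field leaves
    the FA map unchanged."""
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1.0]])
    base = phantom.default_tissue_params()
    rotated = phantom.default_tissue_params()
    for name in rotated:
        rotated[name].fiber = tuple(rot @ np.asarray(rotated[name].fiber))
    spec_a = phantom.PhantomSpec(grid_shape=(24, 24, 3), voxel_size=VOX,
                                 tissue_params=base, rng_seed=0)
    spec_b = phantom.PhantomSpec(grid_shape=(24, 24, 3), voxel_size=VOX,
                                 tissue_params=rotated, rng_seed=0)
    bvecs = phantom.fibonacci_directions(30)
    fa_a = compute_fa(fit_dti(phantom.generate_dti(spec_a, phantom.build_truth(spec_a),
                                                   bvecs=bvecs)))
    fa_b = compute_fa(fit_dti(phantom.generate_dti(spec_b, phantom.build_truth(spec_b),
                                                   bvecs=(bvecs @ rot.T))))
    ok = np.isfinite(fa_a.data)
    assert np.abs(fa_a.data[ok] - fa_b.data[ok]).max() < 1e-6
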