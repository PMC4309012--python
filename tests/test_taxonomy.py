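"""Lesion detection, classification, exclusion and relation rules."""

import numpy as np
import pytest

from mslesion import phantom, taxonomy
from mslesion.grids import VolumeGrid

VOX = (0.9375, 0.9375, 4.0)
PIXEL_AREA = VOX[0] * VOX[1]


def _vol(data):
    return VolumeGrid(np.asarray(data, float), voxel_size=VOX)


# ------------------------------------------------------------- NAWM statistics


def test_nawm_stats_recover_injected_values():
    rng = np.random.default_rng(0)
    data = 85.0 + 3.0 * rng.standard_normal((60, 60, 3))
    wm = np.ones((60, 60, 3), bool)
    stats = taxonomy.estimate_nawm_stats(_vol(data), wm)
    assert np.allclose(stats.mean, 85.0, atol=0.2)
    assert np.allclose(stats.sd, 3.0, atol=0.2)


def test_nawm_stats_unaffected_by_excluded_lesions():
    """With candidate exclusion, stats match truth-mask-based stats to
    within sampling error even when lesions occupy 10% of WM."""
    rng = np.random.default_rng(1)
    sigma = 3.0
    data = 85.0 + sigma * rng.standard_normal((60, 60, 2))
    wm = np.ones((60, 60, 2), bool)
    lesions = np.zeros_like(wm)
    lesions[:19, :19, :] = True  # ~10% of WM
    data[lesions] += 40.0
    stats = taxonomy.estimate_nawm_stats(_vol(data), wm, candidate_mask=lesions)
    n = (~lesions).sum()
    assert abs(stats.global_mean - 85.0) < 0.5 * sigma / np.sqrt(n) * 5
    assert abs(stats.global_sd - sigma) < 0.15


def test_nawm_stats_robust_to_heavily_lesioned_slice():
    """The MAD estimator keeps the threshold anchored to the NAWM bulk
    even when 15% of a slice is (undetected) lesion tissue."""
    rng = np.random.default_rng(2)
    data = 100.0 + 5.0 * rng.standard_normal((80, 80, 1))
    wm = np.ones((80, 80, 1), bool)
    contam = np.zeros_like(wm)
    contam[:31, :31, 0] = True  # 15%
    data[contam] += 25.0
    stats = taxonomy.estimate_nawm_stats(_vol(data), wm)  # no candidate exclusion
    assert stats.mean[0] < 102.5 and stats.sd[0] < 7.5  # threshold still below lesions
    mask, _, _ = taxonomy.detect_flair_hyperintensities(_vol(data), stats, wm)
    assert mask[contam].mean() > 0.8


def test_iterative_stats_converge_quickly_noiseless(four_type_study):
    flair, _, _, truth = four_type_study
    wm, csf = truth.masks.wm, truth.masks.csf
    det = lambda vol, st: (vol.data > st.upper(2.0)) & wm
    stats, mask, n_iter = taxonomy.iterative_nawm_stats(flair, wm, csf, det)
    assert n_iter <= 3
    assert np.array_equal(mask, truth.label_volume >= 10)


def test_nawm_stats_minimum_sample_enforced():
    wm = np.zeros((10, 10, 1), bool)
    wm[:3, :3, 0] = True
    with pytest.raises(ValueError, match="sample voxels"):
        taxonomy.estimate_nawm_stats(_vol(np.ones((10, 10, 1))), wm)


def test_neighborhood_stats_annulus():
    rng = np.random.default_rng(3)
    data = 100.0 + 2.0 * rng.standard_normal((80, 80, 1))
    wm = np.ones((80, 80, 1), bool)
    comp = np.zeros_like(wm)
    comp[38:42, 38:42, 0] = True
    out = taxonomy.neighborhood_nawm_stats(_vol(data), comp, wm)
    assert out is not None
    mean, sd = out
    assert abs(mean - 100.0) < 0.5 and abs(sd - 2.0) < 0.3
    tiny_wm = np.zeros_like(wm)
    tiny_wm[39:41, 39:41, 0] = True
    assert taxonomy.neighborhood_nawm_stats(_vol(data), comp, tiny_wm) is None


# ------------------------------------------------------------------ detection


def test_detection_boundary_is_strict():
    """A voxel exactly at mean+2SD (or mean-2SD) is not flagged."""
    data = np.full((30, 30, 1), 50.0)
    wm = np.ones((30, 30, 1), bool)
    stats = taxonomy.NAWMStats(
        mean=np.array([50.0]), sd=np.array([2.0]), n=np.array([900]),
        sample_mask=wm, global_mean=50.0, global_sd=2.0,
    )
    data[3, 3, 0] = 54.0  # exactly mean + 2SD
    data[4, 4, 0] = 54.0 + 1e-9
    mask, _, n = taxonomy.detect_flair_hyperintensities(_vol(data), stats, wm)
    assert not mask[3, 3, 0] and mask[4, 4, 0] and n == 1
    data2 = np.full((30, 30, 1), 50.0)
    data2[5, 5, 0] = 46.0  # exactly mean - 2SD
    lo = taxonomy.detect_t1_hypointensities(_vol(data2), stats, wm)
    assert not lo.any()


def test_enhancement_requires_signal_increase(four_type_study):
    flair, t1pre, _, truth = four_type_study
    wm = truth.masks.wm
    stats = taxonomy.estimate_nawm_stats(t1pre, wm, truth.label_volume >= 10,
                                         truth.masks.csf)
    same = taxonomy.detect_enhancement(t1pre, t1pre, stats, wm)
    assert not same.any()


def test_enhancement_mask_is_truth_annulus(four_type_study):
    flair, t1pre, t1post, truth = four_type_study
    wm, csf = truth.masks.wm, truth.masks.csf
    candidates = truth.label_volume >= 10
    post_stats = taxonomy.estimate_nawm_stats(t1post, wm, candidates, csf)
    enh = taxonomy.detect_enhancement(t1pre, t1post, post_stats, wm)
    assert np.array_equal(enh, truth.type_volume == 1)


# -------------------------------------------------------------- classification


def test_classification_recovers_types_and_volumes(four_type_study):
    """Noiseless four-phenotype phantom: every truth unit (ring counted
    as annulus + core) gets its declared type; total volumes match the
    truth voxel arithmetic exactly."""
    flair, t1pre, t1post, truth = four_type_study
    table, relations, _ = taxonomy.run_classification(
        flair, t1pre, t1post, truth.masks.wm, truth.masks.csf
    )
    ev = taxonomy.evaluate_against_truth(table, truth)
    assert len(ev) == 5  # 3 simple lesions + ring annulus + ring core
    assert ev.agree.all()
    totals = {t: 0.0 for t in ("active", "t1_hypointense", "t1_isointense")}
    for r in table.records:  # include min-area-flagged caps
        totals[r.lesion_type] += r.volume_mm3
    vox_vol = np.prod(VOX)
    for name, code in taxonomy.TYPE_CODE.items():
        assert totals[name] == pytest.approx(
            float((truth.type_volume == code).sum()) * vox_vol, abs=1e-9
        )


def test_ring_decomposes_into_annulus_and_core(four_type_study):
    flair, t1pre, t1post, truth = four_type_study
    table, _, masks = taxonomy.run_classification(
        flair, t1pre, t1post, truth.masks.wm, truth.masks.csf
    )
    ring = [l for l in truth.lesions if l.true_type == "ring"][0]
    mine = truth.label_volume == 10 + ring.lesion_id
    center_slice = int(round(ring.center[2]))
    types_here = {
        r.lesion_type
        for r in table.records
        if not r.excluded and mine[tuple(r.voxels.T)].any()
        and center_slice in r.areas_mm2
    }
    assert types_here == {"active", "t1_hypointense"}


def test_precedence_enhanced_and_dark_voxel_is_active():
    labels = np.zeros((10, 10, 1), int)
    labels[4:6, 4:6, 0] = 1
    hypo = np.zeros_like(labels, bool)
    hypo[4:6, 4:6, 0] = True
    enh = np.zeros_like(labels, bool)
    enh[4, 4, 0] = True  # both dark on T1-pre and enhancing
    table = taxonomy.classify_lesions(labels, hypo, enh, VOX)
    by_type = {r.lesion_type: r for r in table.records}
    assert by_type["active"].n_voxels == 1
    assert by_type["t1_hypointense"].n_voxels == 3
    # partition: each region voxel appears in exactly one record
    assert sum(r.n_voxels for r in table.records) == 4


# ------------------------------------------------------------------ exclusions


def _toy_table(pixel_counts, positions=None):
    """One slice, one rectangular 'lesion' per entry of pixel_counts."""
    shape = (64, 64, 1)
    labels = np.zeros(shape, int)
    for i, n in enumerate(pixel_counts):
        x = 5 + 10 * i
        labels[x:x + n, 5, 0] = i + 1
    return labels


def test_exclusion_rules_small_and_periventricular():
    """A 4-pixel lesion is excluded, a 5-pixel lesion retained, and a
    lesion within the CSF margin excluded — exact surviving count."""
    shape = (64, 64, 1)
    labels = np.zeros(shape, int)
    labels[5:9, 5, 0] = 1  # 4 pixels
    labels[20:25, 5, 0] = 2  # 5 pixels
    labels[40:45, 40, 0] = 3  # 5 pixels, next to CSF
    csf = np.zeros(shape, bool)
    csf[42, 42, 0] = True  # 2 voxels from lesion 3
    none = np.zeros(shape, bool)
    table = taxonomy.classify_lesions(labels, none, none, VOX)
    table = taxonomy.apply_exclusions(table, csf, min_area_mm2=4.4, csf_margin=2)
    kept = table.retained
    assert len(table.records) == 3
    assert len(kept) == 1
    assert kept[0].n_voxels == 5
    reasons = {r.region_id: r.exclusion_reasons for r in table.records if r.excluded}
    assert reasons[1] == ("min_area",)
    assert reasons[3] == ("csf_proximity",)
    with pytest.raises(ValueError):
        taxonomy.apply_exclusions(table, csf, min_area_mm2=-1.0)


def test_exclusion_flags_preserve_records():
    """Exclusion flags, never deletes: counts are conserved."""
    labels = _toy_table([2, 3, 6])
    none = np.zeros(labels.shape, bool)
    table = taxonomy.classify_lesions(labels, none, none, VOX)
    out = taxonomy.apply_exclusions(table, none, min_area_mm2=4.4)
    assert len(out.records) == len(table.records)
    assert sum(r.n_voxels for r in out.records) == sum(r.n_voxels for r in table.records)


# --------------------------------------------------------- volumes & relations


def test_lesion_volume_arithmetic():
    """Volume = sum of per-section areas x section thickness: two slices
    of 10 and 12 mm^2 at 4 mm give 88 mm^3."""
    shape = (40, 40, 2)
    labels = np.zeros(shape, int)
    n1 = int(round(10.0 / PIXEL_AREA))
    n2 = int(round(12.0 / PIXEL_AREA))
    labels[:n1, 0, 0] = 1
    labels[:n2, 0, 1] = 1
    none = np.zeros(shape, bool)
    table = taxonomy.classify_lesions(labels, none, none, VOX, grid_shape=shape)
    vols = taxonomy.lesion_volumes(table)
    expected = (n1 + n2) * PIXEL_AREA * 4.0
    assert vols.total_mm3 == pytest.approx(expected, abs=1e-12)
    empty = taxonomy.classify_lesions(np.zeros(shape, int), none, none, VOX)
    assert taxonomy.lesion_volumes(empty).total_mm3 == 0.0


def test_combined_load_is_hypo_plus_active_only(clean_study):
    flair, t1pre, t1post, truth = clean_study
    table, _, _ = taxonomy.run_classification(
        flair, t1pre, t1post, truth.masks.wm, truth.masks.csf
    )
    v = table.volumes_by_type()
    assert table.combined_load_mm3 == pytest.approx(
        v["t1_hypointense"] + v["active"]
    )
    assert table.combined_load_mm3 < table.total_load_mm3


def test_spatial_relation_categories():
    shape = (60, 60, 1)
    labels = np.zeros(shape, int)
    enh = np.zeros(shape, bool)
    hypo = np.zeros(shape, bool)
    # overlapping: active on top of hypointense tissue
    labels[5:9, 5:9, 0] = 1
    enh[5:9, 5:9, 0] = True
    hypo[5:9, 5:9, 0] = True
    # adjacent: within the 2-voxel margin of a hypo area
    labels[20:24, 5:9, 0] = 2
    enh[20:24, 5:9, 0] = True
    hypo[25:29, 5:9, 0] = True
    # independent: far from any hypo area
    labels[45:49, 45:49, 0] = 3
    enh[45:49, 45:49, 0] = True
    table = taxonomy.classify_lesions(labels, hypo, enh, VOX)
    rel = taxonomy.spatial_relation(table, hypo, adjacency_margin=2)
    by_region = {r.region_id: r.spatial_relation for r in table.records
                 if r.lesion_type == "active"}
    assert by_region == {1: "overlapping", 2: "adjacent", 3: "independent"}
    assert rel.n_active == 3
    assert sum(rel.percentages.values()) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        taxonomy.spatial_relation(table, hypo, adjacency_margin=-1)


def test_ring_annulus_relation_is_adjacent(four_type_study):
    flair, t1pre, t1post, truth = four_type_study
    table, relations, masks = taxonomy.run_classification(
        flair, t1pre, t1post, truth.masks.wm, truth.masks.csf
    )
    ring = [l for l in truth.lesions if l.true_type == "ring"][0]
    mine = truth.label_volume == 10 + ring.lesion_id
    center_slice = int(round(ring.center[2]))
    # on the section showing annulus + core, the annulus surrounds the
    # hypointense core: adjacent/surrounding
    rels = {r.spatial_relation for r in table.records
            if r.lesion_type == "active" and not r.excluded
            and mine[tuple(r.voxels.T)].all() and center_slice in r.areas_mm2}
    assert rels == {"adjacent"}


def test_false_positive_rate_matches_gaussian_tail():
    """On lesion-free noisy WM the mean+2SD threshold flags ~2.3% of
    voxels before size filtering (moment estimator, one large slice)."""
    rng = np.random.default_rng(5)
    wm = np.ones((320, 320, 1), bool)
    vol = _vol(100.0 + 5.0 * rng.standard_normal(wm.shape))
    stats = taxonomy.estimate_nawm_stats(vol, wm, estimator="moment")
    mask, _, _ = taxonomy.detect_flair_hyperintensities(vol, stats, wm)
    p = 0.0227501
    half = 1.96 * np.sqrt(p * (1 - p) / wm.sum())
    assert abs(mask.sum() / wm.sum() - p) <= half


def test_classification_accuracy_does_not_improve_with_noise():
    """Expected type agreement is non-increasing in noise_sigma."""
    from conftest import make_lesioned_spec

    agreements = []
    for sigma in (0.0, 5.0, 10.0):
        vals = []
        for seed in (21, 22):
            spec = make_lesioned_spec(seed=seed, noise_sigma=sigma,
                                      grid_shape=(64, 64, 8), load_mm3=2000.0)
            flair, t1pre, t1post, truth = phantom.generate_structural(spec)
            table, _, _ = taxonomy.run_classification(
                flair, t1pre, t1post, truth.masks.wm, truth.masks.csf
            )
            vals.append(taxonomy.evaluate_against_truth(table, truth).agree.mean())
        agreements.append(np.mean(vals))
    assert agreements[0] >= agreements[1] - 0.02
    assert agreements[1] >= agreements[2] - 0.02
    assert agreements[0] == 1.0
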