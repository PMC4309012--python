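"""End-to-end orchestration: phantom -> maps -> distortion correction ->
lesion taxonomy -> morphometry -> cohort statistics.

`run_subject` executes the per-subject chain in the acquisition's own
order: parametric maps are computed in EPI (source) space, lesions are
identified and classified on the structural grid, ROIs are carried
through the inverse deformation onto the source grid, and CBV/FA are
quantified on the original, unresampled maps.  `run_cohort` aggregates
subjects and runs the statistical battery (lesion-type comparisons,
volumetrics, spatial relations, load/atrophy/disability correlations).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import distortion, maps, morphometry, phantom, stats, taxonomy
from .fields import DeformationField
from .grids import VolumeGrid

__all__ = ["PipelineParams", "SubjectResult", "CohortResult", "run_subject", "run_cohort"]

WM_ROI_LABEL = 1000


@dataclass
class PipelineParams:
    """Every tunable of the per-subject chain, with study defaults."""

    # DSC protocol / processing
    dsc_n_timepoints: int = 60
    dsc_tr_s: float = 1.9
    dsc_te_s: float = 0.040
    dsc_n_baseline: int = 10
    cbv_mode: str = "trapezoid"
    # taxonomy
    min_area_mm2: float = 4.4
    csf_margin_vox: int = 2
    adjacency_margin_vox: int = 2
    overlap_threshold: float = 0.5
    connectivity: Literal["2d", "3d"] = "2d"
    # distortion handling: "truth" bypasses registration with the known
    # field (separates registration quality from pipeline correctness),
    # "register" runs the elastic registration, "none" assumes no warp
    field_mode: Literal["truth", "register", "none"] = "truth"
    registration: distortion.RegistrationConfig = field(
        default_factory=distortion.RegistrationConfig
    )


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    table: taxonomy.LesionTable
    relations: taxonomy.RelationSummary
    volumetrics: morphometry.VolumetricsRecord
    observations: pd.DataFrame
    truth: phantom.PhantomTruth
    field: DeformationField
    cbv: VolumeGrid
    fa: VolumeGrid
    provenance: dict

    @property
    def combined_load_mm3(self) -> float:
        return self.table.combined_load_mm3


def _compute_maps(spec, truth, params: PipelineParams):
    dsc = phantom.generate_dsc(
        spec, truth,
        n_timepoints=params.dsc_n_timepoints, tr=params.dsc_tr_s,
        te=params.dsc_te_s, n_baseline=params.dsc_n_baseline,
    )
    dti = phantom.generate_dti(spec, truth)
    if spec.deformation_amplitude_mm > 0:
        dsc = phantom.apply_synthetic_distortion(dsc, truth.field)
        dti = phantom.apply_synthetic_distortion(dti, truth.field)
    baseline = slice(0, params.dsc_n_baseline)
    dr2s = maps.compute_delta_r2star(dsc, baseline, params.dsc_te_s)
    cbv = maps.compute_cbv(
        dr2s, slice(params.dsc_n_baseline, dsc.n_frames), mode=params.cbv_mode
    )
    tensors = maps.fit_dti(dti)
    fa = maps.compute_fa(tensors)
    b0 = dti.frame(0)  # registration source for the diffusion chain
    dsc_pre = dsc.frame(0)
    return cbv, fa, b0, dsc_pre


def _classify(flair, t1pre, t1post, truth, params: PipelineParams):
    table, relations, _ = taxonomy.run_classification(
        flair, t1pre, t1post, truth.masks.wm, truth.masks.csf,
        min_area_mm2=params.min_area_mm2, csf_margin=params.csf_margin_vox,
        adjacency_margin=params.adjacency_margin_vox,
        overlap_threshold=params.overlap_threshold,
        connectivity=params.connectivity,
    )
    return table, relations


def _roi_volume(table: taxonomy.LesionTable, wm_mask: np.ndarray) -> np.ndarray:
    rois = np.zeros(table.grid_shape, dtype=np.int32)
    rois[np.asarray(wm_mask, bool)] = WM_ROI_LABEL
    for r in table.retained:
        rois[tuple(r.voxels.T)] = r.lesion_id + 1
    return rois


def run_subject(
    subject: phantom.SubjectRecord, params: PipelineParams | None = None
) -> SubjectResult:
    """Execute the full per-subject chain on one phantom subject."""
    params = params or PipelineParams()
    spec = subject.spec
    flair, t1pre, t1post, truth = phantom.generate_structural(spec)
    cbv, fa, b0, dsc_pre = _compute_maps(spec, truth, params)

    if params.field_mode == "truth" or spec.deformation_amplitude_mm == 0:
        fld = truth.field
    elif params.field_mode == "register":
        fld = distortion.register_elastic(b0, flair, params.registration)
    else:
        fld = DeformationField.identity(spec.grid_shape, spec.voxel_size)

    table, relations = _classify(flair, t1pre, t1post, truth, params)

    rois = _roi_volume(table, truth.masks.wm & (truth.label_volume == 1))
    rois_src, _counts = distortion.transform_rois_inverse(rois, fld)
    cbv_stats = distortion.sample_map_in_rois(cbv, rois_src)
    fa_stats = distortion.sample_map_in_rois(fa, rois_src)
    for r in table.records:
        lab = r.lesion_id + 1
        if lab in cbv_stats and not cbv_stats[lab].empty:
            r.mean_cbv, r.sd_cbv = cbv_stats[lab].mean, cbv_stats[lab].sd
        if lab in fa_stats and not fa_stats[lab].empty:
            r.mean_fa, r.sd_fa = fa_stats[lab].mean, fa_stats[lab].sd

    rows = []
    if subject.group == "control":
        # per-slice normal-WM observations in source space
        wm_src = rois_src == WM_ROI_LABEL
        for k in range(spec.grid_shape[2]):
            sel = wm_src[..., k]
            c = cbv.data[..., k][sel]
            f = fa.data[..., k][sel]
            c, f = c[np.isfinite(c)], f[np.isfinite(f)]
            if c.size and f.size:
                rows.append(
                    {"subject": subject.subject_id, "group": "control",
                     "tissue": "wm", "slice": k,
                     "cbv": float(c.mean()), "fa": float(f.mean())}
                )
    else:
        for r in table.retained:
            rows.append(
                {"subject": subject.subject_id, "group": "patient",
                 "tissue": r.lesion_type, "slice": min(r.areas_mm2),
                 "cbv": r.mean_cbv, "fa": r.mean_fa}
            )
    observations = pd.DataFrame(
        rows, columns=["subject", "group", "tissue", "slice", "cbv", "fa"]
    )

    volumetrics = morphometry.compute_volumes(
        truth.masks, float(np.prod(spec.voxel_size))
    )
    provenance = {
        "subject_id": subject.subject_id,
        "seed": spec.rng_seed,
        "grid_shape": list(spec.grid_shape),
        "voxel_size": list(spec.voxel_size),
        "noise_sigma": spec.noise_sigma,
        "deformation_amplitude_mm": spec.deformation_amplitude_mm,
        "field_mode": params.field_mode,
        "params": {
            k: v for k, v in asdict(params).items() if not isinstance(v, dict)
        },
    }
    return SubjectResult(
        subject_id=subject.subject_id, group=subject.group, table=table,
        relations=relations, volumetrics=volumetrics, observations=observations,
        truth=truth, field=fld, cbv=cbv, fa=fa, provenance=provenance,
    )


@dataclass
class CohortResult:
    cohort_table: pd.DataFrame
    observations: pd.DataFrame
    comparisons: dict[str, stats.ComparisonResult]
    volumetric_comparisons: dict[str, stats.ComparisonResult]
    correlations: dict[str, stats.CorrelationResult]
    relations: stats.RelationPercentages
    subject_results: list[SubjectResult]

    def report(self) -> str:
        lines = ["# Cohort report", "", "## Lesion-type CBV/FA vs control WM", ""]
        for key, c in self.comparisons.items():
            lines.append(
                f"- {key}: diff={c.difference:+.3f} (clustered p={c.p_clustered:.4f}, "
                f"naive p={c.p_naive:.4f}, n={c.n_obs}, clusters={c.n_clusters})"
            )
        lines += ["", "## Volumetrics (patient vs control)", ""]
        for key, c in self.volumetric_comparisons.items():
            lines.append(
                f"- {key}: diff={c.difference:+.1f} mm^3 (p={c.p_clustered:.4f})"
            )
        lines += ["", "## Spatial relation of active lesions", ""]
        if self.relations.defined:
            lines.append(
                f"- adjacent {self.relations.adjacent:.0f}% / overlapping "
                f"{self.relations.overlapping:.0f}% / independent "
                f"{self.relations.independent:.0f}% (n={self.relations.n_active})"
            )
        else:
            lines.append("- no active lesions")
        lines += ["", "## Correlations", ""]
        for key, c in self.correlations.items():
            lines.append(f"- {key}: r={c.r:.2f}, p={c.p:.4f}, n={c.n}")
        return "\n".join(lines)


def run_cohort(
    subjects: Sequence[phantom.SubjectRecord],
    params: PipelineParams | None = None,
    keep_subject_results: bool = False,
) -> CohortResult:
    """Run every subject and the full statistical battery."""
    if not subjects:
        raise ValueError("empty cohort")
    params = params or PipelineParams()
    results: list[SubjectResult] = []
    cohort_rows = []
    obs_frames = []
    tables = []
    for subject in subjects:
        res = run_subject(subject, params)
        lv = res.volumetrics
        cohort_rows.append(
            {
                "subject": res.subject_id, "group": res.group,
                "edss": subject.edss,
                "combined_load_mm3": res.combined_load_mm3,
                "total_load_mm3": res.table.total_load_mm3,
                **lv.as_dict(),
            }
        )
        obs_frames.append(res.observations)
        tables.append(res.table)
        if keep_subject_results:
            results.append(res)
    cohort = pd.DataFrame(cohort_rows)
    observations = pd.concat(obs_frames, ignore_index=True)

    comparisons: dict[str, stats.ComparisonResult] = {}
    ctrl = observations[observations["tissue"] == "wm"]
    for tissue in ("active", "t1_hypointense", "t1_isointense"):
        les = observations[observations["tissue"] == tissue]
        if les.empty or ctrl.empty:
            continue
        both = pd.concat([ctrl, les], ignore_index=True)
        for param in ("cbv", "fa"):
            try:
                # difference = lesion minus control WM
                comparisons[f"{tissue}_{param}"] = stats.compare_groups(
                    both[param], both["tissue"],
                    both["subject"], reference="wm",
                )
            except ValueError:
                pass

    volumetric_comparisons: dict[str, stats.ComparisonResult] = {}
    for col in ("wm_mm3", "gm_mm3", "lateral_ventricle_mm3", "total_ventricle_mm3"):
        try:
            # difference = patient minus control
            volumetric_comparisons[col] = stats.compare_groups(
                cohort[col], cohort["group"], cohort["subject"], reference="control"
            )
        except ValueError:
            pass

    relations = stats.summarize_relations(tables)

    correlations: dict[str, stats.CorrelationResult] = {}
    pat = cohort[cohort["group"] == "patient"]
    pairs = {
        "load_vs_lateral_ventricle": ("combined_load_mm3", "lateral_ventricle_mm3"),
        "load_vs_total_ventricle": ("combined_load_mm3", "total_ventricle_mm3"),
        "lateral_ventricle_vs_edss": ("lateral_ventricle_mm3", "edss"),
        "total_ventricle_vs_edss": ("total_ventricle_mm3", "edss"),
    }
    for key, (a, b) in pairs.items():
        try:
            correlations[key] = stats.correlate(pat[a], pat[b])
        except ValueError:
            pass

    return CohortResult(
        cohort_table=cohort, observations=observations, comparisons=comparisons,
        volumetric_comparisons=volumetric_comparisons, correlations=correlations,
        relations=relations, subject_results=results,
    )


def save_subject_outputs(res: SubjectResult, out_dir: str | Path) -> None:
    """Write the per-subject artifacts: lesion CSV, typed label NIfTI,
    maps, volumetrics row and a JSON provenance record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.table.to_dataframe().to_csv(out / "lesions.csv", index=False)
    label = VolumeGrid(
        res.table.label_volume().astype(float),
        voxel_size=res.truth.voxel_size, units="lesion type code",
    )
    label.to_nifti(out / "lesion_labels.nii.gz")
    res.cbv.to_nifti(out / "cbv.nii.gz")
    res.fa.to_nifti(out / "fa.nii.gz")
    pd.DataFrame([res.volumetrics.as_dict()]).to_csv(out / "volumetrics.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(res.provenance, fh, indent=2)
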