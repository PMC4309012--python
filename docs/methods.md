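# Methods

`mslesion` re-implements, as a tested pipeline, a multimodal MRI analysis
of white-matter lesions in relapsing–remitting multiple sclerosis:
parametric maps of relative cerebral blood volume (CBV, from dynamic
susceptibility contrast perfusion) and fractional anisotropy (FA, from
diffusion tensor imaging), statistical classification of FLAIR-detected
lesions into active, T1-hypointense and T1-isointense types, correction
of EPI geometric distortion with quantification on the unresampled maps,
brain volumetrics, and the cohort statistics relating lesion load, brain
atrophy and disability. Because no patient data accompany the design,
every stage is exercised against a synthetic multimodal phantom with
exact ground truth; this note records the models, the defaults, and what
the phantom does and does not establish about real data.

## Parametric maps

**Relative CBV.** During a gadolinium bolus the transverse relaxation
rate rises by ΔR2\*(t) = −ln(S(t)/S0)/TE, with S0 the mean over the
pre-bolus baseline frames. The first-pass time integral of ΔR2\* is
proportional to the voxel's blood volume, so the map is the trapezoidal
integral over a user-chosen window (default: everything after the
baseline) in *relative units* — no arterial input function is modelled,
matching a design that only ever compares groups. An optional
gamma-variate fit mode integrates a fitted
A·(t−t0)^α·exp(−(t−t0)/β) analytically, which excludes recirculation;
it calls a per-voxel nonlinear fit and is intended for ROI-sized
regions. Voxels with non-positive S0 or S(t) are marked NaN rather than
infinite, and all downstream statistics exclude NaN with counts
reported. Bolus arrival can be detected automatically as the first
frame where the mean brain signal drops more than 3 baseline SDs.

**FA.** The diffusion tensor is fitted per voxel by log-linear least
squares, ln S = ln S0 − b·gᵀDg, over ≥6 non-collinear directions plus
≥1 b=0 frame (protocol default: 55 directions at b = 1500 s/mm² plus
6 b=0 frames). Eigenvalues are sorted descending; negative eigenvalues
are clamped to a 1e−12 floor and the voxel flagged (never discarded, so
ROI means remain computable; the flagged fraction is exposed). FA is

FA = √(3/2) · √(Σᵢ(λᵢ−λ̄)²) / √(Σᵢλᵢ²),

clipped to [0, 1]. The design-matrix condition number is recorded; a
condition above 1e8 (collinear gradients) raises an error. A weighted
or nonlinear fit variant was deliberately left out: at the phantom's
signal-to-noise the log-linear estimator is adequate and exactly
invertible against the generator.

## Lesion taxonomy

Lesions are FLAIR hyperintensities inside the WM mask: voxels strictly
above the NAWM mean + 2 SD. T1-hypointensities are voxels strictly
below NAWM mean − 2 SD on pre-contrast T1. Enhancing (active) tissue is
above NAWM mean + 2 SD on post-contrast T1 *and*, by default, shows a
post-minus-pre increase larger than 2 SD of that paired difference in
the NAWM sample — the second sub-rule guards against tissue that is
bright on both T1 volumes; both sub-rules are configurable. All
boundary comparisons are strict ("higher than" / "lower than").

**NAWM reference.** The reference statistics are estimated slice-wise
from WM voxels excluding lesion candidates and a 2-voxel in-plane CSF
margin, with a global fallback for slices with fewer than 50 sample
voxels. The default estimator is median / 1.4826·MAD, which equals
(mean, SD) for Gaussian data but stays anchored to the NAWM bulk when a
heavily lesioned slice would otherwise inflate the SD past its own
lesions' contrast (a failure mode we observed with moment estimators at
~15% slice lesion load: the detection fixed point then stalls with the
lesions undetected). A `moment` estimator is available, and a
neighborhood mode (WM within a 10–20 mm annulus of a candidate, with
slice fallback) is provided for local referencing. Detection and
estimation alternate until the candidate set stabilises (a fixed point
reached in ≤3 iterations on clean phantoms).

**Classification.** Within each labelled FLAIR component every voxel
receives exactly one type with precedence active > T1-hypointense >
T1-isointense, so a voxel that is both enhancing and T1-dark counts as
active (a configuration the data genuinely contain). Each
(component, type) pair becomes one lesion record; a ring-enhancing
lesion thereby decomposes into an active annulus plus a core typed by
its own T1-pre value. Components are 8-connected within each axial
section by default (evaluation is section-wise; a 26-connected 3-D mode
exists), so a lesion spanning sections contributes one record per
section — the same counting that makes a cohort yield ~10² to 10³
"lesion spots".

**Exclusions.** Records are flagged — never deleted — when every
cross-section is smaller than the minimum area (default 4.4 mm²,
quantized to whole pixels: `round(4.4 / 0.9375²) = 5` pixels, i.e.
"less than 5 pixels" is excluded and exactly 5 retained) or when any
voxel lies within a 2-voxel in-plane dilation of the CSF mask
(partial-volume guard). Flagged records are omitted from all totals.
Volumes are exact arithmetic: per-section area sums times section
thickness, which equals voxel count × voxel volume.

**Spatial relations.** Each retained active record is *overlapping*
when ≥50% of its area lies on T1-hypointense voxels, *adjacent* when
not overlapping but within 2 in-plane voxels of a hypointense area, else
*independent*. The 50% overlap threshold and 2-voxel margin quantify
verbal categories ("exactly at/overlapping", "immediately adjacent
to/surrounding") and are exposed in the configuration and reported.
Percentages are kept unrounded internally; reports round to integers.

## Distortion correction

EPI (perfusion/diffusion) volumes are warped in-plane relative to
structural scans by eddy currents. The correction registers the
pre-contrast perfusion or b=0 volume (source) to the FLAIR/structural
volume (target) section by axial section, in both directions, with
multi-resolution symmetric-forces demons: intensity-difference forces
after per-volume normalization (optionally histogram matching the
source to the target, default on), Gaussian regularization of the
displacement field (default 2 voxels), coarse-to-fine at shrink factors
4/2/1, 100 iterations per level. The two directions are coupled by an
explicit inverse-consistency step — each field is averaged with the
numerical inverse of its counterpart — and the residual of the
composition is recorded on the result.

A B-spline free-form deformation driven by SimpleITK's generic
optimizers was evaluated first and rejected: without a bending-energy
term it overshoots badly in homogeneous white matter (mean field errors
of 1–10 voxels on known 3 mm warps across optimizer/mesh settings),
whereas the demons formulation recovers the same fields at ~0.3–0.45
voxel mean error in a few seconds per volume. The intensity-difference
metric presumes monotone intensity correspondence between source and
target; the phantom is constructed to satisfy this (see below), and
real multi-contrast pairs would need a mutual-information front end.

**Quantification never resamples the maps.** ROIs drawn on the target
grid are carried through the *inverse* mapping onto the source grid
with nearest-neighbour (label-preserving) interpolation, and CBV/FA
statistics are computed on the original map values there; per-label
voxel-count changes are reported. A bypass mode accepts an externally
supplied field (e.g. the phantom truth), separating registration
quality from pipeline correctness in tests.

## Morphometry

Tissue segmentation is an input (ground-truth masks from the phantom,
or any external tool). Volumes are exact voxel counts times voxel
volume, with the composite definitions lateral = right + left lateral
ventricle and total = lateral + third + fourth, asserted as identities.
Lesion candidates outside the WM mask are removed before
classification, with removal counts logged.

## Cohort statistics

Lesion CBV/FA observations arrive as many records per subject
(patients) or per-section WM means (controls), so the headline
comparison is a population-average regression: OLS of the measurement
on group with cluster-robust standard errors by subject. The sandwich
meat uses the bias-reduced CR2 (Bell–McCaffrey) adjustment — each
cluster's residuals rescaled by (I − H_gg)^(−1/2) — referenced against
a t distribution with (clusters − 2) degrees of freedom. Plain CR1 was
measured at empirical type-I error 0.062–0.072 at the 7+7-subject
design with within-subject correlation 0.3; CR2 brings it to ~0.055.
A naive two-sample Welch t-test, a Shapiro–Wilk normality screen and a
Mann–Whitney fallback are attached to every comparison; no
multiple-testing correction is applied by default (a Holm adjustment is
available). Associations between per-subject quantities use the Pearson
correlation with its two-sided test and the fitted line. Degenerate
inputs (identical values, <2 clusters per group, n<3 or zero variance)
are flagged or rejected rather than returning NaN.

## The phantom

The simulator is the test substrate: a simplified supratentorial brain
(elliptical outline, cortical GM shell, WM interior, paired lateral
plus third and fourth ventricles) on the acquisition geometry of the
design — 240 mm axial FOV at 0.9375 mm in plane (the resolution implied
by "5 pixels ≈ 4.4 mm²") and contiguous 4 mm sections. Spherical WM
lesions carry the four phenotypes; signal offsets default to 5σ of the
nominal noise at SNR 20, making per-voxel type misassignment under the
2 SD thresholds a ~0.1% event — conspicuous lesions, by construction
recoverable. Per-type true parameters: hypointense CBV 0.4 (WM = 1),
FA 0.15, MD 1.2e−3 mm²/s; active CBV 1.4, FA 0.20, MD 1.0e−3;
isointense exactly at WM (CBV 1.0, FA 0.45, MD 0.8e−3).

*Noise.* The per-tissue SDs in the configuration are nominal values
used to validate lesion detectability margins; realized voxel noise is
governed by a single `noise_sigma` (additive Gaussian by default, with
a Rician magnitude option), so noiseless phantoms satisfy every
threshold relation exactly and all round-trip tolerances are sharp.

*DSC.* Each voxel's ΔR2\*(t) is a unit-integral gamma variate
(α = 3, β = 2.5 s, onset after a ≥8-frame baseline) scaled by
k·trueCBV with k = 50 s⁻¹·s per unit relative CBV — the integral of
ΔR2\* equals k·trueCBV exactly, so CBV recovery is linear by
construction. TR/TE default to 1.9 s / 40 ms.

*DTI.* Signals follow the monoexponential tensor model with an axially
symmetric tensor built from (FA, MD): with r = λ2/λ1 the prolate FA is
(1−r)/√(1+2r²), inverted through the quadratic
(2FA²−1)r² + 2r + (FA²−1) = 0, root in (0, 1]; λ1 = 3MD/(1+2r). The
construction is exactly invertible, making the generator→fit round
trip a zero-tolerance check. Directions default to a 55-point
Fibonacci hemisphere.

*EPI contrast.* The DSC baseline of lesion tissue equals WM so the
signal-level-dependent noise bias of −ln(S)/TE cancels between lesion
and control-WM ROIs; the diffusion b=0 baseline of lesions is mildly
hyperintense (as on real T2-weighted EPI), which also anchors the
elastic registration inside WM. Ventricles are dark on the synthetic
EPI baselines — monotone with FLAIR — which is what licenses the
difference-based registration metric; real b=0 CSF is bright.

*Deformation fields.* Gaussian-smoothed white-noise displacements
(8-voxel in-plane kernel, mildly smoothed through-plane), scaled so the
largest displacement equals the requested amplitude, rejection-sampled
for strictly positive Jacobians, and paired with a fixed-point
numerical inverse (composition residual < 0.1 voxel). The smoothness
reflects the low spatial order of eddy-current distortion.

*Cohorts.* Latent per-subject variables (lesion load, ventricle
volume, EDSS) are multivariate normal with configurable pairwise
correlations (defaults 0.85 load↔ventricle, 0.80 ventricle↔EDSS) and
map linearly — with mild clipping and half-point EDSS rounding — onto
the generative targets, so Pearson recovery is testable: lesions are
placed until the hypo+active volume reaches the load target, and the
ventricle geometry is scaled to the volume target. Active lesions are
placed with controlled spatial relations (56% adjacent / 40%
overlapping / 4% independent, rings counted as surrounding). Realism
terms added after validating the true-null isointense comparison:
between-subject variation of normal-WM FA (SD 0.012) and CBV (4%),
per-subject scaling of each lesion's *deviation* from that baseline
(SD 15%, leaving WM-equal lesion types exactly null), and pairwise
matching of each control's normal-WM baseline to a patient's —
mirroring an age/gender-matched design; without matching, chance
baseline differences at small n made the true-null comparison
significant in a majority of seeds. Default cohort size is 7 patients
+ 7 controls; the direction-reproduction check uses 24+24 so that
correlation significance reflects the effect sizes rather than
small-sample luck, and the statistical-calibration checks use n = 200
subjects (correlation recovery) and 1000 Monte-Carlo replicates
(type-I error) — desk-scale sizes chosen for sharp checks.

## What the phantom does not show

The phantom has no partial-volume mixing, no anatomical texture beyond
tissue boundaries and lesions, no field-dependent or through-plane
distortion, stylized (monotone) EPI contrast, Gaussian rather than
Rician noise by default, and spherical lesions with piecewise-constant
signals. Passing tests therefore establish the *internal correctness*
of the estimators, thresholds, transforms and statistics at realistic
SNR — not segmentation or registration performance on clinical images,
where NAWM heterogeneity, partial volume and multi-contrast
relationships would dominate.

## Determinism and problem sizes

Every random element derives from named substreams of a single seed
(`numpy.random.SeedSequence`), so identical specifications are
bit-reproducible. Default test problem sizes — 80×80×10 voxel grids,
~30–55 lesions per patient, 10-seed noise ensembles, 1000-replicate
calibrations — keep the full suite within a couple of minutes on one
CPU while leaving every tolerance sharp.
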