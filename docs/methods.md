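# Methods

## Overview

`smileasym` quantifies how differently posed and spontaneous smiles move
the face, and how asymmetric those movements are between the left and
right hemifaces, from 68-point 3D facial landmark tracks plus AU06/AU12
intensities in the OpenFace 2.0 CSV dialect. The analysis chain is:
person-specific neutral reference → fiducial-anchored similarity
registration of every smile frame → per-landmark displacement →
region × hemiface intensity aggregation → within-subject ANOVA
contrasts. A synthetic cohort generator with known ground truth stands in
for study recordings, which are typically not shareable.

## Landmark topology and sides

The package assumes the iBUG-68 annotation (jaw outline 0–16, eyebrows
17–26, nose 27–35, eyes 36–47, mouth 48–67), the scheme OpenFace emits.
The published region decompositions in this literature usually show only
an index diagram, so the exact sets are a convention of this package:
primitive regions outline / eyebrow_left / eyebrow_right / eye_left /
eye_right / nose / mouth partition 0..67, with composites eyebrow, eye,
upper_face (eyebrow ∪ eye) and lower_face (nose ∪ mouth ∪ outline).

"Left" means the subject's anatomical left throughout, because the
hemispheric-lateralization questions this analysis feeds are anatomical;
`RegionMap.flipped()` converts observer-perspective data. Strictly
midline landmarks (chin tip 8, nose bridge 27–30, nose-base centre 33,
mid-lip 51/57/62/66) belong to neither hemiface, which keeps every
region's left/right cardinalities equal — hemiface intensities therefore
compare like with like. Both the region map and the fiducial set
serialize to YAML so alternative annotation schemes can be supplied.

## Registration

Each smile frame is registered onto the subject's neutral reference by
the weighted least-squares similarity transform over the fiducial
landmarks only (defaults: nose bridge 27–30 and inner eye corners 39/42,
uniform weights — no published evidence suggests non-uniform ones, but
they are configurable). These landmarks barely move with expression, so
anchoring on them removes head pose while leaving expression intact; the
generator enforces this by never displacing fiducials, and the test suite
checks that intensities are invariant to arbitrary rigid motions of the
input frames.

The solver is the standard SVD/Kabsch construction with the
determinant-correction diagonal diag(1, 1, det(VUᵀ)), which guarantees a
proper rotation (det R = +1) even for reflection-dominated inputs, plus
the Umeyama least-squares scale s = tr(ΣD) / Σwᵢ‖pᵢ−p̄‖² and
t = q̄ − s·R·p̄. Scale absorbs small camera-distance and calibration
differences between recordings; `with_scale=False` disables it for
strictly rigid registration. Some published statements of this algorithm
print a scale formula of the form (p̄ᵀq̄)/n, which is dimensionally
inconsistent and not the least-squares optimum; this package implements
the least-squares form that the underlying rigid-motion derivation
(Sorkine-style) actually yields.

Numerical choices: orthogonality and determinant of every returned
rotation are asserted at 1e-6 (achieved in practice at ~1e-12); exact
noise-free recovery is tested at 1e-6 with residuals below 1e-9 mm
(double-precision SVD headroom); fewer than three fiducials or a
collinear configuration raises (the in-plane rotation would be
undetermined, detected via a rank test on the centred fiducials).
Degenerate det(VUᵀ) = 0 falls back to +1. An independent brute-force
oracle (10⁴ sampled rotations, each with closed-form optimal t and s)
bounds the solver from above in the tests and the acceptance script.

Frames whose detector flag is false or whose confidence falls below 0.75
(configurable) are skipped and logged, mirroring the quality exclusions
such studies apply at acquisition.

## Neutral reference

The reference is the coordinate-wise median over the subject's
quality-passing neutral frames — robust to blinks and micro-expressions.
Because neutral frames each carry their own head pose, they are first
co-registered onto the first neutral frame (`aligned_neutral_reference`);
taking a raw median across differently posed frames would smear the
template and inflate every downstream displacement. Displacements are
thus measured in the subject's neutral-face geometry.

## Displacement intensity

For an aligned frame, dᵢ = ‖p̂ᵢ − qᵢ‖ (mm). A (region, side) intensity
sums dᵢ over the region ∩ side indexes per frame and averages over
frames. Summing (rather than averaging) per landmark makes larger regions
carry proportionally larger intensities, which matches how region-level
smile-intensity tables in this literature scale (a 20-landmark mouth
dwarfs a 9-landmark nose); the frame-mean makes recordings of different
lengths comparable. A per-landmark "mean" mode is available. With the
default sum mode, composite-region intensities are exactly additive in
their primitive parts, which the tests exploit as an invariant. Units are
whatever the landmarks are in (mm for OpenFace 3D output).

The evaluation metric for landmark accuracy is the size-normalized error
ε = (1/L) Σ d(x̃ᵢ, xᵢ)/d_scale, with d_scale the interocular distance
(distance between the mean points of the two 6-landmark eye rings) by
default. The quantity is often *called* a median error while being
written as a mean; the mean is the default here and a median variant is a
flag.

## Statistical model

Per region, per subject, the four cells (posed/spontaneous ×
left/right) form a 2×2 within-subject design. With two levels per
factor, each repeated-measures ANOVA effect is algebraically a paired t
test on a within-subject contrast — expression: ((S_L+S_R) −
(P_L+P_R))/2; side: ((P_L+S_L) − (P_R+S_R))/2; interaction: (S_L−S_R) −
(P_L−P_R) — with F = t² on (1, n−1) df. Sphericity is trivially
satisfied at two levels, so no Greenhouse–Geisser correction applies.
This contrast formulation is exact (cross-checked against pingouin's
general RM-ANOVA in the tests) and behaves sensibly in degenerate cases:
an all-zero contrast gives F = 0, p = 1; a constant non-zero contrast
with zero variance gives F = ∞, p = 0.

Post-hoc pairwise comparisons are paired t tests with Bonferroni
adjustment p_adj = min(1, m·p_raw). The default family (m = 4) is the
expression simple effect within each side plus the side simple effect
within each condition; the family is configurable because published
analyses rarely state their m. Subjects missing any cell are excluded
whole (complete-case analysis). α = 0.05 throughout; summary tables
report raw p values with conventional stars so readers can apply their
own convention.

The AU analysis is the one-factor special case on per-subject mean
AU06_r / AU12_r / their sum over quality-passing frames, optionally
baselined by subtracting the subject's neutral-condition means (clipped
at zero — negative AU intensity is meaningless). Whether published AU
means are baselined is usually unstated, so both modes exist; the
pipeline defaults to baselining, which is the person-specific
normalization the displacement analysis also embodies.

## Synthetic cohort generator

Each frame is built as template + subject offset + expression field,
pushed through a rigid pose and landmark noise:

* **Template**: a fixed, bilaterally symmetric 68-point neutral face
  (literal coordinates, interocular distance 63 mm — an adult average).
* **Subject shape offset**: one Gaussian offset per subject (sd 2 mm per
  coordinate), shared by all of that subject's frames — the
  person-specific geometry that the neutral-reference normalization must
  cancel.
* **Expression fields**: fixed unit directions per region (brow/eye raise
  +y; mouth corners lateral+superior; jaw outline lateral), scaled by
  per-landmark magnitudes in mm. Defaults: eyebrow 1.0 posed / 2.0
  spontaneous, eye 0.5/1.0, mouth 4.0/2.5, outline 1.0/2.0, nose 0/0,
  plus a +0.5 mm left-eyebrow bias — the direction pattern the analysis
  is designed to detect (upper face spontaneous-dominant, mouth
  posed-dominant, left eyebrow > right, silent nose). A per-subject
  amplitude factor (Gaussian around 1, sd 0.3, floored at 0.1) models
  between-subject expressiveness and supplies realistic between-subject
  variance for the ANOVA.
* **Pose**: per-frame uniform Euler angles within ±10°, translation
  within ±20 mm, scale in [0.97, 1.03].
* **Noise**: isotropic Gaussian, sd 0.5 mm — the order of landmark
  detector jitter on 3D output.
* **AU intensities**: per-subject condition means drawn around posed
  (AU06 0.03, AU12 0.74) and spontaneous (AU06 0.35, AU12 0.09) with
  between-subject sds (0.07, 0.54, 0.29, 0.15), per-frame jitter sd 0.1,
  truncated at 0 to respect the OpenFace 0–5 floor.
* **Sizes**: 57 subjects by default (a typical cohort for such studies);
  15 frames per condition, representing smile-apex frames sampled from a
  recording — enough frames for the frame-mean to stabilise while
  keeping replicated simulation studies cheap.
* **Reproducibility**: a single root seed spawns per-subject seeds;
  identical spec + seed gives byte-identical CSVs.

What the generator does *not* emulate: temporal dynamics (onset/apex/
offset), anatomically realistic deformation bases, correlated landmark
noise, detector dropouts beyond the success/confidence flags, or AU-to-
landmark coupling. Passing tests therefore demonstrate that the pipeline
recovers known rigid motion and additive displacement fields under
Gaussian noise and reports calibrated statistics — not that it handles
non-rigid detector artefacts of real video.

## Validation studies

Two replicated studies back the statistical claims (run by both the test
suite and `scripts/acceptance.py`):

* **Null calibration**: 2,000 replicates of an exchangeable Gaussian
  null at n = 57 — each effect's rejection rate at α = 0.05 must stay in
  [0.04, 0.06] (binomial tolerance at 2,000 replicates).
* **Power and directions**: 200 replicated default cohorts at n = 50 —
  detection of the upper-face expression effect and the eyebrow side
  effect in the injected direction with power ≥ 0.9, all injected
  main-effect directions reproduced, and the nose expression effect (a
  true null carried through the entire pipeline) rejecting in
  [0.02, 0.08].

## Known limitations

* The similarity transform cannot absorb non-rigid head/skin deformation;
  residual non-rigid motion leaks into displacement intensities.
* Sum-mode intensities depend on the region index sets; results are
  comparable only under a fixed region map.
* The 2×2 contrast machinery is deliberately restricted to two-level
  within-subject factors; multi-level factors or between-subject
  covariates need a general mixed-model package.
* Intensities are not normalized by face size; cross-cohort comparisons
  should either enable registration scaling (default) or normalize by
  interocular distance.
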