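# smileasym

Landmark-based analysis of posed versus spontaneous smiles from 3D facial
landmark recordings.

Genuine (spontaneous, "Duchenne") smiles engage the muscles around the
eyes — the orbicularis oculi, coded as action unit AU06 — in addition to
the lip corner puller (zygomatic major, AU12), while deliberately posed
smiles are dominated by mouth movement. These differences, and the
left/right asymmetries that come with them, can be quantified from
68-point 3D facial landmark tracks (the iBUG-68 scheme that OpenFace 2.0
emits) without any video: `smileasym` measures, per subject, how far each
landmark moves from that subject's own neutral face during each smile,
aggregates the movement by facial region and hemiface, and tests the
posed-vs-spontaneous and left-vs-right contrasts with within-subject
ANOVA. It is aimed at affective-computing and behavioural researchers who
have per-frame landmark + AU tables (one CSV per subject × condition) and
want region-level smile-asymmetry statistics.

## Method

**Registration.** Head pose differs between recordings, so raw landmark
differences confound expression with pose. Each smile frame *p* is
registered onto the subject's neutral reference *q* using only a set of
expression-stable *fiducial* landmarks — nose bridge (27–30) and inner eye
corners (39, 42) — by the weighted least-squares similarity transform

```
argmin_{R ∈ SO(3), t, s>0}  Σᵢ wᵢ ‖ s·R·pᵢ + t − qᵢ ‖²
```

solved in closed form: R from the SVD of the weighted cross-covariance of
the centred fiducials with the determinant correction diag(1, 1,
det(VUᵀ)) that excludes reflections, the least-squares (Umeyama) scale
s = tr(ΣD)/Σwᵢ‖pᵢ−p̄‖², and t = q̄ − s·R·p̄. Because the anchors do not
move with expression, the residual expression signal survives the
registration intact.

**Displacement intensity.** After alignment, dᵢ = ‖p̂ᵢ − qᵢ‖ is landmark
i's displacement for that frame. A (region, hemiface) intensity is the
sum of dᵢ over the region∩side index set per frame, averaged over the
recording's frames. The neutral reference itself is the coordinate-wise
median of the subject's co-registered neutral frames.

**Statistics.** Per region, intensities form a 2×2 within-subject design
(expression: posed/spontaneous × side: left/right). Both factors have two
levels, so each repeated-measures ANOVA effect is exact: F = t² on
(1, n−1) df, where t is the paired t statistic of the effect's
within-subject contrast. Pairwise post-hoc paired t tests use Bonferroni
adjustment (p_adj = min(1, m·p_raw), default family m = 4). AU06/AU12
condition means (optionally baselined against the subject's neutral
recording) are compared with the one-factor equivalent.

**Synthetic cohorts.** Because this kind of study data is rarely
shareable, `smileasym.simulate` generates OpenFace-dialect cohorts with
known ground truth — a symmetric template face, per-subject shape
offsets, region-specific expression displacement fields, rigid head
poses, landmark noise, and AU intensities — so the whole pipeline can be
validated end to end.

## Worked example

```python
import smileasym as sa
from smileasym.pipeline import intensity_table_from_cohort

spec = sa.CohortSpec(n_subjects=12, seed=7)     # synthetic study, 12 subjects
cohort = {}
for i in range(spec.n_subjects):
    sub = sa.simulate_subject(spec, i)
    cohort[sub.subject_id] = sub.frames

table, residual = intensity_table_from_cohort(cohort)
print(f"mean fiducial residual: {residual:.3f} mm")

results = sa.RegionAsymmetryModel(
    table, regions=("eyebrow", "eye", "nose", "mouth", "upper_face")
).fit()
print(results.summary())
```

prints

```
mean fiducial residual: 0.638 mm
Two-way repeated-measures ANOVA (expression x side), n = 12 subjects

region      effect                F       df          p  direction
------------------------------------------------------------------
eyebrow     expression        44.36   (1,11)    3.6e-05***  Spontaneous > Posed
eyebrow     side              21.56   (1,11)    0.00071***  Left > Right
eyebrow     interaction        5.55   (1,11)      0.038*    Interaction
eye         expression        23.98   (1,11)    0.00047***  Spontaneous > Posed
eye         side               0.63   (1,11)       0.44     Not significant
eye         interaction        1.83   (1,11)        0.2     Not significant
nose        expression         3.09   (1,11)       0.11     Not significant
nose        side               1.22   (1,11)       0.29     Not significant
nose        interaction        1.64   (1,11)       0.23     Not significant
mouth       expression        87.91   (1,11)    1.4e-06***  Posed > Spontaneous
mouth       side               0.81   (1,11)       0.39     Not significant
mouth       interaction        0.02   (1,11)       0.89     Not significant
upper_face  expression        38.47   (1,11)    6.7e-05***  Spontaneous > Posed
upper_face  side               7.17   (1,11)      0.022*    Left > Right
upper_face  interaction        4.10   (1,11)      0.068     Not significant
```

The mean fiducial residual is the average distance left on the anchor
landmarks after registration — a registration-quality diagnostic (here
dominated by the 0.5 mm simulated landmark noise). The F table shows the
injected pattern being recovered: spontaneous smiles move the upper face
(eyebrow, eye) more than posed smiles, posed smiles move the mouth more,
the left eyebrow moves more than the right, and the nose — which carries
no expression — shows nothing.

The same analysis is available from the shell:

```
smileasym simulate --n-subjects 12 --seed 7 --out cohort/
smileasym intensity cohort/ --out intensity.tsv
smileasym analyze intensity.tsv --out-dir stats/
```

or end to end with `smileasym run --config cfg.yaml` on real OpenFace
CSVs listed in a manifest.

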