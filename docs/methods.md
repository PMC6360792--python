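# Methods

This note records the models, conventions and design choices behind
`sinumetry`, in the package's own words.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The DRM and its assumptions

The diameter ratio measurement treats the pooled arithmetic mean of the
maxillary and sphenoid sinus diameters, normalised by skull reference
diameters, as a proxy for sinus size on one scan.  Its validity rests on
three assumptions: (i) adult skull landmarks do not change over the
observation period, so the denominator is a stable yardstick; (ii) healthy
adult sinuses keep a constant size, so a flat DRM series means no disease
progression; (iii) osteitis shrinks the air space roughly uniformly enough
that a mean of many diameters tracks it.  The method is by construction
unsuitable for children (physiological sinus growth violates ii) and is
confounded by expansile lesions (see the mucocele archetype below).

Two deliberate conventions:

* **Pooling.**  The numerator is a single pooled mean over every present
  diameter, not a mean of per-sinus means.  A missing value (for example a
  scan with only one imaging plane) then simply shrinks the pool rather than
  invalidating a sinus; `pooling="per_sinus"` switches to the nested
  alternative, which weights sinuses equally but is fragile under
  missingness.
* **Reference denominator.**  Both reference diameters — the axial
  inter-orbital distance and the coronal skull width — are averaged by
  default; `reference_mode="axial"` uses the axial one alone.  The two
  references are measured in different planes precisely so that a
  single-plane scan still yields a denominator.

## Trajectory slopes

Per patient, DRM is regressed on elapsed time in decimal years (365.25
days) since that patient's first scan, by unweighted ordinary least squares
solved in closed form.  The slope β₁ (ΔDRM) is the progression rate in
ratio units per year; per-year units make slopes comparable across patients
and are recorded in the output metadata.  `residual_sd` is
√(RSS/(n−2)) for n > 2 and exactly 0 at n = 2.  Same-day repeat scans are
retained; the design is degenerate only when *all* dates coincide.  No
robust or weighted variant is offered: the trajectory model is deliberately
a plain straight line, and patients whose series cannot be fitted are
reported, never silently dropped.

## Scoring

* **GOSS subscores** come from a (wall thickness band × extent band) lookup
  shipped as an editable, YAML round-trippable table.  The default bands are
  <3 mm, 3–5 mm and ≥5 mm crossed with involvement below/at-or-above 50%,
  scoring 1/2, 3/4 and 5/5 respectively; a wall of 5 mm or more always
  scores the maximum 5, which is the scale's ceiling.  A thickness below
  1 mm, or zero involvement, scores 0 ("no osteitis"): normal sinus walls
  are thin, and the 1 mm floor is a protocol choice carried by the config
  table, not hard-coded.  The table loader rejects any non-monotone
  replacement.
* **Grade bands** on the total: the printed bands overlap at 20 and 35; the
  implementation uses none < 5, mild [5, 20], moderate (20, 35], severe
  (35, 50], consistent with "severe" being defined as a total above 35.
* **Sinus vocabulary.**  The 10 scored units are the paired frontal,
  anterior ethmoid, posterior ethmoid, maxillary and sphenoid sinuses; this
  naming lives in one tuple shared by GOSS and Lund–Mackay and can be
  audited in `sinumetry.scoring`.
* **Aplasia** is an explicit flag: an aplastic sinus must carry subscore 0
  and downstream users can exclude it.  Surgical and inflammatory structure
  loss are not separated in the destruction sheet — one boolean per item,
  18 items (10 sinus-wall items, nasal septum, hard palate, 6 conchae).

## Classification

The grouping applies two rules in order: last-CT GOSS = 0 → *no osteitis*
(whatever the slope, which also keeps non-osteitic size loss out of the
disease groups); otherwise ΔDRM at or above the median split → *stable*,
below → *progressive*.  Ties go to stable.  The median is taken over the
whole cohort's slope distribution by default and then applied to the
GOSS-positive subset (`median_scope="goss_positive"` restricts the
reference set; `threshold=` replaces the median with a fixed external value
so that single new patients can be classified against a historical cohort).
A cohort-relative median is a relative, not an absolute, definition of
progression: the label *progressive* means "declining faster than the
cohort's typical patient", and the split value is therefore always reported
alongside the labels.

## Phantom volumetry

Phantoms are ellipsoidal cavities (air, −1000 HU) in a bone-valued grid
(+700 HU) with optional soft-tissue filling (+40 HU) and i.i.d. Gaussian HU
noise, rendered deterministically per seed.  Segmentation takes the
26-connected component of {HU ≤ −400} containing a seed voxel.  Numerical
choices: the threshold is **inclusive** (a voxel at exactly −400 HU is
cavity) and connectivity is 26; both choices move single boundary voxels
only, far below the 5% volumetric tolerance used throughout.  No
partial-volume modelling: voxels are single-valued plus noise, so the
segmentation error is a surface-voxel effect that vanishes as the voxel
size shrinks (checked by a refinement test).  An opacified (soft-tissue
filled) cavity is invisible to thresholding by construction — the
generator's known geometry then stands in for manual contouring.

The VRM divides the mean cube root of the present sinus volumes by the mean
reference diameter.  Cube roots are averaged **before** division; the
construction mirrors the DRM's pooled-mean-over-reference form.  Volumes
scaled by k³ with references scaled by k leave the VRM unchanged.

## Agreement and reliability

* **Bland–Altman**: differences a−b, sample SD, limits of agreement at
  mean ± 2·SD (the multiplier is exactly 2, not 1.96, matching the
  two-standard-deviations convention).  Pairs with |diff − mean| > 3·SD are
  flagged as outliers in the returned table but never removed
  automatically; removal is a reviewed, manual act.
* **Inter-reader ICC**: variance components for patients, readers within
  patients, and replicate residual, estimated by ANOVA method of moments —
  closed-form, dependency-light, unbiased on balanced designs; mild
  imbalance is handled by an unweighted-means approximation with harmonic
  mean cell sizes.  Negative moment estimates are truncated at zero.  ICC =
  var_patient / (var_patient + var_reader + var_residual).  REML through
  `statsmodels` MixedLM is available as `method="reml"`, and a crossed
  readers-by-patients layout as `design="crossed"`; nested is the default
  because reader calibration is typically re-established per patient in
  retrospective serial-CT reading.
* **Intra-reader ICC**: each reader's replicates are decomposed into
  between-patient and within-patient variance (one-way, per reader) and the
  components pooled across readers; a reader's own systematic offset does
  not penalise their repeatability, so the reader component is reported as
  zero in the intra-reader result.

## The synthetic cohort generator

The generator emulates five trajectory archetypes — healthy controls, GPA
without osteitis, stable osteitis, progressive osteitis, and a mucocele
patient whose GOSS rises while the DRM does not fall.  Per patient: a true
linear DRM (baseline + slope·t), scan dates with the first at t = 0, the
last at the drawn observation span and interior dates uniform (irregular
follow-up without modelling visit processes), individual diameters
disaggregated from a fixed per-sinus profile scaled so the pooled ratio
reproduces the true DRM exactly before noise, and i.i.d. Gaussian noise per
diameter and per reference.  Optional whole-plane missingness exercises the
missing-value contract of the DRM.

Key defaults (all overridable in `CohortConfig`): baseline DRM 0.40 ± 0.04
(pooled diameter mean ≈ 43 mm against references of 95 and 120 mm); 3–9
scans per patient over 3–10 years; flat-group slopes N(0, 0.002)/yr;
progressive slopes N(−0.022, 0.004)/yr truncated above at −0.010/yr;
mucocele slope +0.008/yr; diameter noise SD 1.0 mm, reference noise SD
0.5 mm.  These produce per-patient slope estimates with standard errors
near 0.001/yr, so the flat and declining clusters are well separated.

**Group sizes.**  Defaults are 15 controls and 30/19/50 GPA patients in the
no-osteitis/stable/progressive groups plus 1 mucocele patient (counted as
stable ground truth).  The progressive patients are deliberately half of
the classified cohort: a cohort-median split can only recover generated
labels when the median falls in the gap between the declining and the flat
slope clusters, which requires the decliners to make up about half the
cohort.  With stable slopes centred at zero — which they must be, since
"stable" means unchanged size — any composition in which decliners are well
under half places the median inside the flat cluster and a fraction of
stable patients below it by construction, regardless of measurement
precision.  The defaults therefore prioritise identifiability of the
ground truth over mimicking any particular observed cohort composition;
all sizes are plain config fields.

**The size-comparison study** (`simulate_size_comparison`) gives each
patient four ellipsoidal sinuses whose semi-axes shrink proportionally,
axes(t) = axes₀·(1 − k·t), with a patient-level rate k ∈ [0.004, 0.022]/yr.
Its diameter protocol (three principal diameters per sinus plus middle
widths) is calibrated per patient so the baseline pooled diameter mean
equals the baseline mean cube-root volume — the same comparability the cube
root is introduced to provide.  Under proportional shrinkage the two ratio
measures then share the same true slope and their Bland–Altman difference
is pure measurement noise, which is what the agreement check measures.
With additive wall thickening instead of proportional shrinkage the two
slopes would differ by a shape-dependent factor of order 20%; the
proportional model is the generator's simplification, not a claim about
anatomy.

**What passing tests do and do not show.**  The generator draws every
diameter from the exact linear model plus Gaussian noise: no reader
drift, no scanner changes mid-series, no correlated per-scan errors, no
opacification hiding diameters, no surgical interventions, and no children.
Recovery and agreement results on these cohorts demonstrate the estimators
and rules are implemented correctly and behave as designed under their own
assumptions — not that real clinical series satisfy those assumptions.

## Problem sizes

The test suite and the acceptance script use: 1000 random series for the
slope-exactness check; one 85×93×105-voxel phantom at 0.5 mm for the
volumetry check; 40 patients × 5 scans for the diameter/volume agreement
study; 100 replicate cohorts of 40 GPA patients for classification
recovery; and 200 replicate balanced reader studies (20 patients × 2
readers × 2 replicates) per generating ICC ∈ {0.5, 0.75, 0.91}.  These
sizes keep each check's Monte-Carlo error well below its decision margin
while the whole suite runs in well under a minute.

## Known limitations

* The DRM is cohort-calibrated only through the median split; absolute
  slope magnitudes depend on the time unit and measurement protocol and are
  not transferable without metadata.
* The exact anatomical definition of the fifth maxillary diameter is a
  measurement-protocol concern; the package validates diameter counts and
  positivity, not anatomy.
* ICC confidence intervals (bootstrap or otherwise) are not provided.
* Phantoms are isotropic and noise-stationary; slice-thickness artefacts
  and inter-timepoint registration are out of scope (phantom series share a
  frame by construction).
* DICOM ingestion of real scans is out of scope; the input boundary is the
  long-format measurement CSV.
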