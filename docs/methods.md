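# Methods

This note records the models, parameter choices and numerical decisions
behind `mibgcal`, and what the synthetic-data-based tests do and do not
demonstrate about real data.

## Digital calibration phantom

The physical calibration object is a flat 380 × 380 × 50 mm acrylic slab
whose compartments mimic the planar ¹²³I-MIBG distribution in heart,
mediastinum, liver, lungs and thyroid, built so the heart/mediastinum
ratio presented to the camera is 2.60 (anterior) and 3.50 (posterior).
Because the calibration mathematics consumes only the two per-view
measured HMRs, each view is modelled as an independent 2D relative-
activity map: the anterior/posterior difference is baked into the
per-view heart density rather than into depth-dependent attenuation, and
the posterior layout is the exact column mirror of the anterior one.

Compartment geometry is this package's own simple construction (the
designated ratios are the only normative constraint): a rectangular body
outline (300 × 320 mm), a 60 mm heart disc left of the midline centered
175 mm below the top edge, a 40 × 80 mm midline mediastinal box, lung
ellipses, a thyroid ellipse and a liver slab in the lower half. Relative
densities are mediastinum 1.0, heart = designated ratio, liver 3.0,
thyroid 2.0, lungs 0.5, background 0.3 — only the heart/mediastinum pair
matters. Masks are painted in priority order (heart first) so they are
disjoint by construction. Two choices deserve mention:

* The mediastinal compartment is 40 mm wide rather than a minimal
  30 mm. The fixed 20 × 60 mm mediastinal ROI then has ≥10 mm margins,
  so geometric blur drains the heart ROI (5 mm margins) relatively
  faster than the denominator — which is what makes the measured HMR a
  monotone function of collimator resolution. With 5 mm margins on both
  ROIs the numerator and denominator losses can trade places and the
  design-sweep ordering becomes fragile.
* The heart center sits at 45% of the body height so the template
  search region ("upper body half, heart side of the midline") contains
  the entire near-maximal response plateau of the disc template.

Designated-ratio reproduction is exact (to 1e-9) at any admissible pixel
size because the reference ROIs are strictly interior to uniform
compartments.

## Planar camera model

Full photon transport and energy-spectrum simulation are out of scope;
the simulator reproduces the *directions* of collimator and acquisition
effects with a three-part analytic model. The expected image is

```
E = S [ (1 − f) · G_geo ⊗ A  +  f · G_haze ⊗ A ]
```

* **Geometric resolution.** `G_geo` is a Gaussian PSF with
  FWHM = d (L_eff + z)/L_eff for hole diameter d, source distance z and
  effective length L_eff = L − 2/μ₁₅₉ (clamped to ≥ L/2). Septal lead
  attenuation defaults are μ₁₅₉ = 2.3 mm⁻¹ and μ₅₂₉ = 0.17 mm⁻¹,
  configurable per collimator.
* **Septal penetration.** The minimal septal path of a 529 keV photon is
  w = L·t/(2d + t); the penetrating fraction of detected counts is
  f = b₅₂₉·a·e^(−μ₅₂₉ w) / (b₅₂₉·a·e^(−μ₅₂₉ w) + b₁₅₉) with branching
  b₅₂₉ = 0.0139, b₁₅₉ = 0.833 and a window-acceptance factor
  a = (half-width %)/7.5, linear in the photopeak window half-width.
  `G_haze` is a Gaussian of fixed 150 mm FWHM. The haze width is a fixed
  physical scale, not a multiple of the geometric FWHM: a haze
  comparable in size to the phantom structures merely redistributes
  counts locally — it can drain the narrow mediastinal valley faster
  than the heart and *raise* the ratio — and a haze width coupled to the
  hole diameter makes the HMR non-monotone in d through the haze-width
  channel. A detector-scale fixed width yields HMR strictly decreasing
  in the penetration fraction.
* **Count statistics.** S scales E to activity × duration × 60.06
  counts/(MBq·s), chosen so the reference protocol (55.5 MBq, 5 min)
  yields 1.0 × 10⁶ counts. Blur pushed off the field of view is
  renormalized back, so the expected total is conserved exactly. With
  noise on, pixels are independent Poisson draws from a generator seeded
  per acquisition (same seed ⇒ bit-identical image); with noise off, E
  is rounded half-to-even to keep count images integral.

**Count quantization.** The noise-free phantom image is piecewise
constant, so rounding maps whole compartments to the same integer (at
10⁶ total counts the mediastinum level is 31.5 → 32, a 1.6% step).
Consequences: designated-ratio checks simulate a 3600 s calibration
acquisition, long enough that quantization is below 0.2% per level; and
the collimator-design sweep evaluates the *expected* float image in the
phantom's reference ROIs, because sub-count differences between
neighbouring designs are otherwise invisible. The sweep also uses the
known reference ROI geometry rather than re-detecting ROIs per design,
isolating collimator physics from discrete placement jumps.

The model's fidelity claim is deliberately narrow: penetration fraction
ordering (LEHR > LMEGP > MEGP), HMR ordering and monotonicity in
(d, t, L), window-width and distance behavior, and linearity of measured
vs designated ratio. Absolute degradation magnitudes of physical cameras
(conversion coefficients of 0.5–0.9) are *not* reproduced — the
simulated coefficients stay near 1 — so every multicenter quantity is
driven by the synthetic registry's planted distributions, not by the
simulator.

## Automatic ROI placement

1. **Body outline**: threshold at 5% of the 99th-percentile count on an
   image smoothed with a 5 mm Gaussian, keeping the largest connected
   component. Smoothing averages Poisson noise; the component rule stops
   stray haze counts from stretching the bounding box. The 5% level sits
   midway between the off-body level (~0) and the body-background level
   (~10% of the maximum), so the outline is stable under quantization —
   a threshold at exactly 10% ties with the background compartment and
   flickers with rounding.
2. **Heart**: a disc template (fixed 25 mm radius) is scanned over the
   upper body half on the heart side of the midline; the center is the
   centroid of all positions within 85% of the maximal template
   response. On an ideal rendering the template response has a flat
   plateau of maxima; a lexicographic tie-break would select the plateau
   edge and push ~3% of the ROI outside the heart compartment, biasing
   HMR by ~0.07. The centroid is exact on the plateau and stable under
   noise.
3. **Mediastinum**: a fixed 20 × 60 mm box centered on the body-midline
   column, its top 60 mm below the detected body top — inside the
   mediastinal compartment with 10 mm margins for any in-field phantom
   translation.

All constants are keyword arguments. HMR uses unweighted means per ROI
(ratio independent of ROI pixel count on homogeneous regions); ties at
the classification threshold count as normal.

The linearity check (measured vs designated ratio through (1, 1),
R² > 0.999, slope = end-to-end CC within 2%) places the ROI once on the
designated-ratio image — the calibration protocol's own placement — and
reuses it across heart densities. Re-detecting per density breaks down
at designated ratio 1.5, where the heart is barely hotter than the
thyroid and the template's near-maximal set spans both.

## Calibration and standardization

CC = ((HMR_Ant + HMR_Post)/2 − 1)/2.05 exactly; no clamping (pathological
values are flagged, not altered, for QC). Standardization
HMR_std = CC_std/CC_i (HMR_i − 1) + 1 with CC_std = 0.88; values below 1
are preserved. The implementation keeps full float precision; two-decimal
rounding happens only in table rendering.

## Multicenter QC pipeline

Records are excluded by the first matching rule, in the order: scatter
correction applied → matrix 64/128 → minor energy window (anything but
159 keV ± 10% or ± 7.5%, centers matched exactly; missing counts as
minor) → minor collimator/camera (vendor-specific list; Hitachi systems
wholesale; unknown names with a warning) → failed experiment →
conversion-coefficient outlier → (optionally) 159 keV ± 7.5% window.
The tally partitions the input exactly.

Outliers use Tukey fences (Q1 − 1.5 IQR, Q3 + 1.5 IQR; interpolated
quartiles) within each collimator group; groups under 4 members are
never flagged. `detect_cc_outliers` is one-pass, but `qc_filter`
iterates it to a fixed point: removing an extreme value shrinks the
fences, so a single pass is not idempotent, whereas the fixed point
makes re-filtering the eligible output a no-op on any input.

Aggregation is the arithmetic mean, sample SD and n of CC per
(vendor, camera model, collimator group) cell, with absent cells
rendered "–" and two-decimal display.

## Synthetic data

`generate_database` emits a 1648-record registry with the study's
stratum composition: 145 scatter-corrected, 79 small-matrix, 297 minor
energy windows (with the per-setting breakdown, including 4 missing), 14
minor-equipment records, 22 failed runs, 20 planted CC outliers, 366
records at 159 keV ± 7.5%, and 705 eligible records split over the seven
collimator groups with their published mean/SD (the ME/MEGP/MEGAP count
is 180 rather than 179 so the groups sum to 705). Coefficients are
back-solved to (HMR_Ant, HMR_Post) = (1 + 1.6 CC, 1 + 2.5 CC),
preserving the designated excess proportions so the calibration formula
recovers the planted CC to machine precision.

Records that reach the outlier-detection stage draw their coefficients
from shuffled *quantile grids* of a normal truncated at ±2 SD — one
complete grid per stratum and group. A quantile grid pins the sample
extremes at the truncation bound while the sample Tukey fence sits near
±2.56 SD, so no inlier can be fence-flagged at any seed, both in the
pooled first pass and when the eligible records are re-filtered alone.
Planted outliers are displaced ≥3 SD beyond the nominal fence,
alternating sides. Strata that never reach outlier detection use plain
truncated draws.

`generate_clinical_set` emits two images (early/delayed) per subject for
12 heart-failure and 21 normal subjects across two hospitals with the
published coefficient pairs (A: 0.631 institutional / 0.621 multicenter;
B: 0.840 / 0.838). True reference-scale HMRs are drawn per stratum
(heart failure N(1.6, 0.25) truncated to [1.2, 2.0]; normal N(3.0, 0.3)
truncated to [2.7, 3.6]) and de-standardized through the hospital's
institutional coefficient. The truncation bands guarantee no un-planted
image crosses a threshold pair under either coefficient source; the
reference layout then plants four heart-failure and one normal image at
hospital B inside the flip band [2.17, ≈2.42), reproducing the
published reclassification outcome (4/24 up among events, 1/42 up among
nonevents, no downward moves; NRI = 14.3%).

What passing these tests shows: the pipeline's algebra, ordering and
filter logic are correct on data with the study's exact composition.
What it does not show: behavior on real registries — vendor-specific
naming noise, per-institution correlation, non-normal coefficient
scatter and genuinely ambiguous outliers are not emulated, and the
published camera-level means enter as generator inputs, not as
independent measurements.

## NRI

NRI = [(up_e − down_e)/n_e − (up_ne − down_ne)/n_ne] × 100, where "up"
is movement toward the abnormal class — an improvement for events
(heart failure) and a worsening for nonevents. Early and delayed images
of one subject are treated as independent observations (image-level
counts). Only the point estimate is computed; no significance test is
attached.

## Known limitations

* The simulator's degradation magnitudes are far milder than physical
  cameras'; it must not be used to predict absolute conversion
  coefficients, only orderings and trends.
* Automatic ROI placement assumes the phantom layout (hottest upper-
  half structure = heart, midline mediastinum); it is not a clinical
  ROI algorithm, and the clinical module deliberately consumes
  precomputed HMR tables instead.
* Attenuation and scatter inside the phantom slab, 3D geometry, and
  detector-crystal effects are not modelled.
* The classification thresholds 2.17/2.49 and the reference coefficient
  0.88 are adopted constants; deriving them (ROC analysis, reference
  cohorts) is outside this package.
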