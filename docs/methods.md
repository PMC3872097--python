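# Methods

## The diagnostic model

The package treats a tendon ROI as a bag of grayscale pixels and its
population standard deviation (StdDev) as a one-dimensional diagnostic
score.  The underlying generative picture is binormal: within each
view the StdDev score of the tendinitis group and of the
non-tendinitis group is modeled as normal, with parameters

| view | tendinitis (n = 136) | non-tendinitis (n = 200) |
|---|---|---|
| transverse | 30.1 ± 6.8 | 21.9 ± 4.1 |
| longitudinal | 26.5 ± 6.0 | 18.7 ± 4.7 |

Under this model the AUC has the closed form
Φ(Δμ/√(σ₊² + σ₋²)) — 0.849 transverse, 0.847 longitudinal — and the
Youden-optimal threshold solves the density-equality condition
f₊(t) = f₋(t), a quadratic when the variances differ; the J-maximizing
root is 26.55 (transverse) and 22.99 (longitudinal).  These closed
forms are the reference points for every stochastic check in the test
suite: the synthetic generator *is* the binormal model, so simulated
cohorts are compared against the theory values its parameters imply,
not against any particular finite-sample realization.

## ROI geometry

ROIs are specified by physical area (default 2.0 mm²) and rasterized
with the pixel-center-in-region rule: a circle (transverse view)
includes a pixel iff its center lies within radius √(area/π) of the
ROI center measured in mm; a square (longitudinal view) is an
axis-aligned block of round(√area/spacing) pixels per axis, its
centroid placed nearest the requested center with ties toward smaller
indices.  The closed-disk boundary rule makes the one-pixel degenerate
case non-empty.  A mask that would leave the image raises rather than
clipping silently.

The protocol's ">2000 pixels" floor is advisory: at 2 mm² it requires
spacing ≲ 0.03 mm/px, which on clinical hardware corresponds to a
zoomed capture.  Synthetic fixtures default to 0.02 mm/px
(≈ 5000 px per ROI) so the constraint is satisfiable literally;
`validate_roi` warns, never fails, when a mask misses the floor or
deviates more than 5% from the target area.

## Echotexture statistics

min/max are exact integers, mean and StdDev floats; StdDev uses the
population convention (÷ n), matching what a PACS ROI tool reports for
the drawn region.  With n > 2000 the population/sample distinction is
below 0.03% (√(n/(n−1)) − 1), asserted in the suite so the choice
cannot affect any tolerance.  Statistics operate on raw integers — no
smoothing, normalization or gain correction, since the method applies
none.  A 256-bin histogram path recomputes identical statistics and
exists for plotting/inspection.

## Reference labeling

The rule-based reference criteria are: sheath swelling at sex-specific
thresholds (transverse ≥ 4.6 mm women / 5.5 mm men; longitudinal
≥ 2.5 / 2.8 mm, inclusive as printed) OR displaceable and compressible
sheath fluid ≥ 3 mm — AND increased Doppler color flow, which is
treated as essential and therefore AND-ed (a `require_color_flow=False`
switch relaxes this, since the prose leaves room for reading the
Doppler finding as corroborative rather than mandatory).  Doppler
processing itself is out of scope; the finding enters as a boolean.
The quantitative classifier is strictly greater-than at the cut-off
("surpassing" the threshold), pinned by a boundary test.

The longitudinal cut-off is fixed at 21.25: the source tables and
abstract agree on it, while one results sentence prints 23.25 — likely
a transcription slip, though notably close to the binormal-theory
optimum (22.99) implied by the group parameters.

## Calibration numerics

* Threshold candidates: midpoints between consecutive distinct scores
  plus sentinels one unit beyond each extreme.  With strict ">"
  positivity this scans every achievable confusion table and yields
  non-data cut-offs (e.g. 26.85 lies between observed values).
* J ties break toward higher specificity, then the lower threshold —
  deterministic, and consistent with the specificity-heavy transverse
  operating point.
* AUROC SE: Hanley–McNeil with Q₁ = A/(2−A), Q₂ = 2A²/(1+A); the CI is
  the normal approximation clipped to [0, 1].  SPSS's nonparametric SE
  differs in the third decimal at these n.
* The logistic screen is per-predictor univariate (intercept + one ROI
  statistic), fitted by Newton/IRLS, convergence at max |Δcoef| < 1e-8
  within 25 iterations; SEs from the inverse observed information;
  the Wald statistic (β/SE)² is referred to χ²(1).  Complete
  separation is flagged `converged=False` rather than erroring.
* Group tests: pooled-variance two-sided t; 2×2 Pearson χ² without
  continuity correction (at the study's n the correction moves the sex
  comparison's p by < 0.01).

## The synthetic generator

`simulate_scores` draws per-subject scores directly from the binormal
model (truncated to [0, 255] by redraw — immaterial at these
parameters).  `simulate_tendon_image` renders an image whose centered
ROI realizes a requested (mean, StdDev):

* **Mixture model.**  ROI pixels come from three normal components
  sharing one per-pixel spread (`speckle_sd`, default 8 gray levels):
  baseline tendon speckle, a hypoechoic fluid component (mean 45, near
  the tendinitis group's ROI minimum) and a hyperechoic component
  (mean 200, near its maximum).  Given the component means, the two
  mixture-moment equations (mean = Σfᵢμᵢ, second moment = Σfᵢ(σᵢ²+μᵢ²),
  f_base = 1 − f_fluid − f_hyper) are a 2×2 linear system in the two
  fractions; infeasible targets raise with the violated bound named.
  Gaussian speckle is a deliberate first-two-moments proxy for
  Rayleigh/log-compressed speckle: the method consumes nothing beyond
  those moments.
* **Spatial structure.**  Fluid pixels form one or two contiguous
  blobs grown from random points on the ROI margin (mimicking sheath
  effusion abutting the tendon); hyperechoic pixels form
  fiber-direction streaks.  Per-pixel mixture identity — and hence the
  moment calibration — is unaffected by where components sit.
* **Fibrillar bands.**  The longitudinal view adds a sinusoidal
  row-wise modulation (amplitude 6, period 0.4 mm) to the baseline;
  its variance contribution A²/2 is included in the baseline
  component's second moment so banded images still hit their targets.
* **Study generation.**  `simulate_study` anchors each image's
  baseline mean at its group's published ROI mean (transverse
  112.4/111.8, longitudinal 102.9/94.2), so the mixture's net mean
  shift is ≈ 0 and any drawn StdDev at or above the speckle floor
  (√(σ² + A²/2) ≈ 8–9) is feasible.  Draws below that floor — about
  2% of the longitudinal non-tendinitis group, negligible elsewhere —
  are clamped up to floor + 0.3; downstream analyses always use the
  achieved image statistics, never the drawn targets.  Demographic
  fields follow the published group summaries; criteria fields
  (sheath, fluid, Doppler) are drawn to agree with the group label for
  95% of subjects, the remaining 5% flipped to emulate equivocal
  presentations.  One root seed derives independent per-image streams
  from (subject, view), making whole studies byte-reproducible.

What passing tests show — and don't.  Synthetic images share the real
data's first-order ROI statistics and their group structure, so they
exercise the full geometry → statistics → calibration chain.  They do
not contain anisotropy dropout, shadowing, depth-dependent gain,
probe-pressure variation or inter-operator ROI placement error, so
agreement on synthetic cohorts says nothing about robustness to those
effects on clinical images.

## Problem sizes and tolerances

Pre-registered simulation tolerances: image-level medians over 50
seeds within ±1.0 (mean) and ±1.5 (StdDev) of target at 0.02 mm/px —
the discretization/rounding budget; cut-off recovery over 500
simulated 136/200 cohorts within ±1.5 of the binormal optimum
(finite-sample Youden maximization is biased upward by ~0 to +0.3
here); large-sample checks use 200 000 draws per group (AUROC sampling
SE ≈ 0.0006).  The end-to-end image-pathway check pools 10 independent
136/200 studies: a single cohort's AUROC SE (~0.023) would exceed the
0.02 agreement band being demonstrated, while the pooled SE (~0.007)
sits well inside it.  The full default suite runs in about a minute on
one core.

## Known limitations

* The binormal score model and the intensity-mixture construction are
  this package's own; only their summary moments and the direction of
  the group contrasts (max ↑, min ↓, mean ≈ constant, StdDev ↑ in
  tendinitis) are anchored to published data.
* Second-order texture (co-occurrence contrast/energy/homogeneity) is
  explicitly out of scope, as are tear/calcification imaging, Doppler
  signal processing, and automatic tendon segmentation.
* `criteria_label` needs sex; cohorts without it cannot be
  reference-labeled.
* The DICOM route (PixelSpacing → sidecar) is intentionally not
  implemented; convert to PNG/TIFF + JSON sidecar first.
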