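# Methods

## The phantom model

An ascending aorta (AA) is modelled as an elliptical tube swept along a
planar circular arc from the sinotubular junction (STJ, arc-length
fraction `s = 0`) to the brachiocephalic trunk (BT, `s = 1`). The arc
bends 60° over its length — a representative AA curvature chosen so that
perpendicular-plane logic is genuinely exercised; a straight tube would
not test it. Four profiles over `s` define the tube, each a monotone
piecewise-cubic (PCHIP) interpolant through a small set of knots, so knot
values are met exactly and no interpolation overshoot can create spurious
diameter maxima:

- `dmax(s)` — maximal diameter (mm);
- `ovality(s)` — `(Dmax − Dmin)/Dmax`, bounded to [0, 0.15];
- `phase_offset(s)` — systolic-minus-diastolic diameter decrement (mm);
- `rotation(s)` — in-plane major-axis angle (rad), 0 by default: the
  orientation of mild ellipticity is not a measured quantity here, so a
  constant orientation is the simplest defensible choice (the hook exists
  for sensitivity studies).

Two presets encode the median dilated ("dg", 79 mm long, peak 43.1 mm at
`s = 0.48`) and nondilated ("ndg", 67 mm, peak 37.2 mm at `s = 0.50`)
aorta in systole; diastole subtracts a linearly tapering offset
(0.5→0.3 mm dilated, 0.3→0.2 mm nondilated). Diameter knots sit at the
segment boundary planes and the interior peak, so the segmental shape
metrics evaluated analytically on the presets reproduce the calibration
values (14.0 % / 18.0 % for segment A, 4.80 % / 7.80 % for segment C,
5.20 / 7.60 mm absolute differences, 8.9 % / 9.4 % STJ ovality) to three
significant figures — this is asserted in the test-suite independently of
any rasterization.

### Virtual cohorts

`sample_cohort` draws per-patient geometry around the group preset:

- a multiplicative diameter scale, lognormal with median 1 and log-SD set
  from the reported group quartile ratios (`σ = ln(Q3/Q1)/1.349`),
  rejection-sampled so the group's diameter criterion (dilated: peak in
  [40, 50] mm; nondilated: < 40 mm) always holds;
- total length, normal around the preset length with SD = IQR/1.349,
  clipped to [52, 110] mm (two 25 mm segments must fit);
- age by inverse-transform sampling through a monotone quantile function
  anchored at median 80 and quartiles 78/85 years, rounded to whole
  years. A parametric skew family cannot reach this quartile asymmetry
  ((Q3−med)/(med−Q1) = 2.5), so the quantile anchors are the model;
- sex Bernoulli(0.54 male); BSA normal(1.8, 0.15) truncated to
  [1.4, 2.4] m²;
- per-patient stochastic phase offsets, uniform 0.1–0.7 mm at 13 knots
  along the vessel.

All draws flow from one `numpy` Generator per cohort, so a cohort is
reproducible field-by-field from its seed.

### Rasterization

A voxel is lumen if its center lies inside the swept tube; the tube is
capped flush with the STJ and BT planes. Membership is evaluated against
a 0.1 mm-resampled centerline with a parallel-transport (rotation
minimising) frame; mask volumes agree with the analytic tube volume to
within 2 % at the default 0.5 mm isotropic voxels (near clinical CTA
reconstruction resolution, kept isotropic for simplicity). Masks carry
their spacing in the NIfTI affine; landmarks are emitted in world mm.

What the phantom does *not* emulate: CT intensities, noise, or contrast
(masks are clean binary), cardiac-phase reconstruction artefacts, the
aortic root and arch beyond the two landmarks, wall thickness (the truth
is lumen-only), calcification, and AA angulation/longitudinal motion.
Passing tests therefore validate the measurement pipeline's geometry, not
segmentation robustness on real CTA.

## Centerline extraction

1. Interior Euclidean distance transform of the mask (mm spacing).
2. Minimum-cost path between the landmark-nearest voxels with per-voxel
   cost `1/(1 + dist²)` (26-connected, geometrically weighted), which
   hugs the lumen center.
3. Centroid refinement: a least-cost path still cuts bends slightly
   toward the inner curve (≈ 2 mm for a 60° bend at 0.5 mm voxels), so
   path points are iteratively moved to the centroid of their
   perpendicular lumen cross-section. Moves are clamped to one voxel per
   iteration (up to 10 iterations, early exit on convergence, revert on
   divergence) because a single oblique early cut can throw a centroid
   far off-axis.
4. Cubic smoothing spline, smoothing factor halved until the maximum
   deviation from the refined path is below one voxel; endpoints pinned
   to the supplied landmark coordinates (the path's own ends sit at voxel
   centers and would bias the arc length short by up to half a voxel per
   end).
5. Arc-length resampling at 0.5 mm.

On phantoms this recovers the true axis to < 0.3 mm and tangents to < 1°,
and re-extraction from a re-rasterized tube built on an extracted
centerline changes the arc length by < 1 %.

## Plane measurement

The mask is sampled on a 0.25 mm 2D grid in the cutting plane (trilinear
interpolation), the grid enlarged once if the section touches its border.
The connected region containing the centerline point is kept and its
subvoxel 0.5-level contour extracted. Two anti-aliasing steps suppress
the voxelisation ripple of the level set, which otherwise biases the
maximal Feret diameter up and the minimal caliper width down by
0.1–0.3 mm: a 1-pixel Gaussian blur of the sampled field, and a Fourier
low-pass of the contour (8 harmonics kept over 512 uniform arc-length
samples — an ellipse needs 2; 8 preserves mild lobulation). `Dmax` is the
maximal pairwise distance of hull points, `Dmin` the minimal width over
hull-edge directions (rotating calipers), area by the shoelace formula.
These definitions coincide with the ellipse axes for elliptical sections;
for the centroid-chord alternative the difference is negligible below
10 % ovality.

Planes within 1.25 voxels of a tube cap cannot be sampled directly (the
interpolated field decays across the cap and truncates the section), so
boundary planes are linearly extrapolated from two interior planes
(1.25 voxels and 2.5 mm further in). Verified accuracy on 0.5 mm phantom
masks: diameters within ±0.15 mm, ovality within ±0.3 percentage points,
areas within 2 %.

## Segments and shape metrics

Segment A planes sit at `s = 0, 5, …, 25` mm; segment C at
`L−25, …, L` mm; an aorta shorter than 50 mm is rejected (segments would
overlap). The relative difference uses systolic `Dmax` of the boundary
planes with the larger plane as denominator (segment A: plane 6; segment
C: plane 1). Classification calls a segment cylindrical when the relative
difference is below 2 % — no real segment in the study conditions is, so
the threshold only guards degenerate inputs. The maximal-diameter sweep
steps 1 mm; ties break toward the most proximal station. Ovality uses
`Dmax` as denominator, consistent with the segment formulas; a
smaller-denominator variant exists in the literature and would give
slightly larger values.

## Cohort statistics

- **Eligibility**: records carry exclusion flags (LVEF < 30 %,
  calcinosis > 30 %, connective-tissue disease, annuloaortic ectasia,
  prior heart surgery, incomplete imaging); flagged records are dropped
  with a per-reason log. The default generator raises no flags so the
  eligible cohort sizes are exact; a configurable exclusion rate
  exercises the bookkeeping.
- **Matching**: Mahalanobis distance on (age, sex as 0/1, BSA) with the
  covariance pooled over all eligible patients; optimal 1:2 assignment by
  replicating each case twice and solving the rectangular assignment
  problem (Jonker–Volgenant), which is exactly the global optimum for
  fixed-ratio matching without replacement. Verified against a bitmask
  dynamic-programming brute force on instances up to 5 cases × 12
  controls.
- **Group contrasts**: two-sided Mann–Whitney U, exact when both groups
  have n ≤ 8 without ties, else the tie-corrected normal approximation;
  Pearson chi-square without continuity correction for categorical
  variables. Exactness thresholds are set so the toy oracle tests run on
  the exact path.
- **Paired contrasts**: two-sided Wilcoxon signed-rank, zeros dropped,
  exact for ≤ 12 informative untied pairs; all-zero differences return
  p = 1. Percentile bootstrap (1000 replicates, seeded) for the 95 % CI
  of the median difference; the percentile flavour is the simplest
  interval consistent with a median functional.
- **Agreement**: ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — computed from the two-way ANOVA mean squares (and
  cross-checked against an independent implementation in the tests), plus
  Bland–Altman mean difference and ±1.96 SD limits.
- No multiple-testing adjustment: p-values are descriptive.

The cohort pipeline computes plane tables analytically from each
patient's parametric profiles rather than rasterizing a hundred volumes;
the geometric pipeline is validated separately on the presets and
phantoms, and the statistical layer consumes plane tables regardless of
their origin. Reported study sizes: archetype geometry at 0.5 mm voxels,
cohorts of 35 + 100 patients, 2000 null simulations for test calibration
and 500 for bootstrap coverage.

## Known limitations

- Flush-capped tubes make the boundary planes extrapolated rather than
  directly measured; real vessels continue past the landmarks, so on real
  masks the cap logic simply never triggers.
- The centroid refinement assumes a roughly convex, single-lumen section;
  bifurcations and dissection flaps are out of scope.
- Voxel masks below ~0.3 mm/voxel resolution or tubes narrower than
  ~20 mm have not been validated at the stated tolerances.
- The phase labels "systole"/"diastole" are geometric presets, not
  reconstructions; dynamic wall motion beyond a diameter offset is not
  modelled.
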