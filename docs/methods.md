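# Methods

## Scope and input model

`hallerquant` consumes already-extracted en face slabs of the top 25% of
Haller's layer: 8-bit grayscale rasters in which large choroidal vessels
are the *dark* phase, row 0 is the superior edge, and (for a right eye)
columns run nasal→temporal.  Slab selection from the OCT volume, Bruch's
membrane flattening, and choriocapillaris/Sattler analysis are out of
scope.  The default pixel pitch is 7/512 mm (a 7 × 7 mm field at 512 × 512
px); every metric scales exactly with `pixel_size_mm`, so other scan
widths only need that one override.

## Vessel segmentation and structure metrics

1. **Binarization** — local-mean (Niblack-style) thresholding: a pixel is
   vessel if its intensity falls below the mean over a `window_px` square
   minus `offset`.  Defaults: window 51 px (≈ 0.7 mm, several vessel
   widths, small enough to ride illumination gradients), offset
   0.1 × image SD (so a featureless scan yields an empty mask instead of
   speckle).  Vessels are dark, so the comparison is one-sided below.
2. **Boundary smoothing** — a median filter with a disk footprint
   (radius `smooth_px`, default 1) applied to the binary mask.  Noise-ragged
   edges are not cosmetic: thinning a ragged ribbon sprouts short spurs,
   and on synthetic scenes at default noise these inflated measured vessel
   length by 30–60%, collapsing the diameter estimate.  Radius 1 removes
   the raggedness while biasing recovered diameters by only a few percent;
   radius 0 disables the step.
3. **De-noising** — 8-connected foreground components with area strictly
   below `min_component_px` (default 100 px ≈ 0.0019 mm²) are removed;
   4-connected, border-free background holes strictly below `min_hole_px`
   (default 100 px) are filled.  Nothing else changes, by contract.
4. **Thinning** — Lee's medial-axis thinning (scikit-image,
   `method="lee"`).  Zhang's variant occasionally leaves fully-foreground
   2 × 2 blocks at dense crossings, which breaks the strict
   one-pixel-wide skeleton contract the segment decomposition relies on.
5. **Metrics** — area = foreground count × pitch²; length is a step-sum
   over skeleton adjacencies: 1 step per orthogonal pair, √2 per diagonal
   pair, *except* that a diagonal adjacency whose two pixels share an
   orthogonal skeleton neighbor is skipped (it is a staircase shortcut,
   not a centerline step — without this rule an L-corner would measure
   √2 − 1 too long, and pixel counting instead of step-summing would
   overestimate diagonal runs by up to 41%).  Mean diameter = area/length;
   a zero-length network raises a distinct undefined-diameter error.

An image whose segmentation is empty (or yields no usable segments)
produces a record flagged `valid=False` with NaN metrics — never zeros,
which would silently poison cohort statistics downstream.

## Symmetry index

Laterality is normalized first (left-eye images mirrored so temporal is
always +x); normalization precedes thinning because thinning is not
mirror-equivariant, and doing it in this order makes an OD image and its
mirrored OS twin bit-identical through the whole pipeline.

Branch pixels (≥ 3 skeleton neighbors in 8-connectivity) are removed; each
remaining 8-connected component with two endpoints and ≥ `min_segment_px`
pixels (default 5 — shorter fragments are thinning artifacts at this
scale) becomes one segment.  Closed loops have no endpoints and are
discarded with a counter.  Pixel accounting is conserved exactly: segment
pixels + branch pixels + discarded pixels = skeleton pixels.

A junction appears as a small *cluster* of branch pixels (even an ideal
one-pixel cross has five pixels with ≥ 3 neighbors), so per-junction
counts are reported as 8-connected clusters.

Each segment's orientation is the undirected angle of its endpoint chord,
folded to (−90°, 90°]; hemifield is assigned by the side of the horizontal
fovea line its path midpoint falls on (on-line midpoints count as
inferior; segments are not split at the midline).  The natural-oblique
band is the full open quadrant per hemifield — superior (0°, 90°),
inferior (−90°, 0°) — with exactly horizontal/vertical segments excluded
by default (`inclusive` widens the band to closed intervals).  Treating
both hemifields symmetrically keeps the mirror invariance exact.  The
fovea defaults to the image center (macula-centered scans) and is
overridable.

Index = 100 × Σ length(natural) / Σ length(all retained); zero retained
segments raise an undefined-index error.

## Synthetic scenes

`generate_vessel_image` draws dark vessel trunks as width-`w` random walks
on a bright background, split at the fovea line into superior and inferior
hemifields.  Per hemifield, exactly `round(s × n_trunks)` trunks take a
base orientation from the natural band (magnitude uniform on 15°–75°) and
the rest from the mirrored band; the stratified split (rather than
Bernoulli draws) keeps the dial `s` an exact ground truth at realistic
trunk counts.  Headings jitter with a mean-reverting walk bounded by
`tortuosity_deg` per step; walks stop at the hemifield boundary or image
edge.  Defaults — 16 trunks per hemifield, width 11 ± 2 px (≈ 0.15 mm),
background 200, vessel 60, additive Gaussian noise SD 20 — produce scenes
with vessel area ≈ 18–20 mm² and skeleton length ≈ 130–165 mm on the
7 × 7 mm field, the scale reported for real Haller-layer slabs.

What the scenes do **not** emulate: OCT speckle statistics, depth-blended
shadows of Sattler-layer vessels, physiological branching trees, or
vessel-caliber tapering.  Passing recovery tests therefore demonstrates
correctness of the measurement chain on controlled geometry, not clinical
performance on scanner images.

Known bias: at realistic densities vessels cross, the mask fuses at
crossings, and `area/length` under- or over-shoots the drawn width by a
few percent (mean ≈ +4% at defaults, within ±13% over widths 9–15 px and
seeds tested); the tests' 15% recovery band reflects this geometry, not
measurement noise alone.

## Synthetic cohorts

`generate_cohort` samples per-eye records per group from truncated-normal
marginals (area, length > 0; symmetry ∈ [0, 100]; CCT > 0) coupled by a
Gaussian copula.  Mean diameter is *derived* as area/length so the record
is always self-consistent.  Because of that, the requested diameter–CCT
Spearman correlation cannot be set directly: the latent area–CCT
correlation is solved by bisection (40 iterations on a fixed-seed latent
sample of 20,000; cached per parameter set) so the derived diameter
attains the target.  Targets outside the achievable range — e.g. a
near-perfect diameter–CCT correlation with near-constant area but widely
varying length — raise `InfeasibleCorrelationError` with the achievable
interval.  Rank correlations are converted to latent Pearson values by
r = 2 sin(πρ/6), exact for Gaussian copulas.

Default group moments (control / fellow / CSC): vessel area 23.4 ± 3.3 /
26.4 ± 4.8 / 27.4 ± 4.7 mm²; vessel length 164.7 ± 24.5 / 156.6 ± 20.5 /
150.0 ± 17.1 mm; symmetry index 59.4 ± 5.8 / 55.3 ± 7.2 / 53.7 ± 6.0%;
CCT 259 ± 87 / 343 ± 100 / 391 ± 101 µm; diameter–CCT Spearman targets
0.746 / 0.775 / 0.745, symmetry–CCT 0 / −0.405 / −0.660.  A negative
control-group length–CCT coupling (−0.364) is included because with the
control group's coefficient of variation the strong diameter–CCT target
is unattainable through area alone.  The derived diameter then lands at
0.147 ± 0.036 (control) and 0.185 ± 0.039 mm (CSC); the control SD is
wider than a clinical cohort's because it is an emergent ratio of two
sampled marginals, a known limitation of deriving rather than sampling
the diameter.

## Cohort statistics

All tests are two-sided at α = 0.05, with no multiple-testing correction.
Mann-Whitney U uses exact enumeration when the pooled size is ≤ 16 with no
ties and the tie-corrected normal approximation otherwise; the reported U
is the first sample's.  The 2 × 2 χ² applies Yates continuity correction
(df = 1).  Spearman uses midranks with the t-approximation p.

`roc_youden` evaluates every observed value as a cutoff with a
strictly-greater positivity rule (an eye is called diseased when its value
exceeds the cutoff), maximizes J = sensitivity + specificity − 1, breaks
ties toward the larger cutoff (higher specificity), and integrates AUC by
trapezoid with the all-positive corner appended.  A 10⁻¹² tolerance when
collecting the argmax keeps mathematically tied J values tied under
floating-point noise.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is bit-reproducible.
The test suite runs scenes at 512 × 512 px, cohort checks at 41/group with
100 replicates and marginal checks at 10,000/group; the brute-force ROC
oracle covers 1,000 random instances of n ≤ 50 and the Mann-Whitney
enumeration all size pairs up to 8 + 8.  `scripts/acceptance.py` uses the
same sizes.

## Known limitations

- The binarization/de-noising defaults are reasoned stand-ins, not a
  reimplementation of any vendor or in-house software; all are
  configurable.
- Whether vessel length should count skeleton pixels or geometric path
  length is a genuine modeling choice; the step-sum here is the geometric
  option and is internally consistent with the diameter definition.
- Midline-crossing segments are assigned wholly to the hemifield of their
  midpoint; splitting them at the fovea line is not implemented.
- The cohort generator reproduces moments and rank correlations, not the
  joint distribution of real eyes; group-level inferences drawn from it
  validate the statistical machinery, not clinical effect sizes.
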