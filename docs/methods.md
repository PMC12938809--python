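# Methods

## Problem and coordinate conventions

On an AP radiograph of a hip prosthesis, the femoral head projects as a
bright disc and the acetabular cup rim as a bright arc/annulus around it;
polyethylene wear is the slow migration of the head inside the cup between
exams. All geometry here is 2D and lives in image coordinates: x rightward,
y downward, 0-based pixel indices, circle centers continuous (sub-pixel).
Under y-down coordinates the superior (top) point of a circle is
`y_top = cy − r`; this convention is load-bearing for the superior-wear
component below.

Annotations are stored resolution-independently: `x = cx/W`, `y = cy/H`,
`r = r_px / ((W+H)/2)`. The mean-dimension denominator makes the radius
unitless without preferring either axis; it is applied literally for all
aspect ratios. The circumscribing normalized box of a circle is
`w = r(1 + H/W)`, `h = r(1 + W/H)`, which guarantees the pixel-space box
side is exactly `2 r_px` on both axes — the identity the ROI-to-circle
proposal inverts (`r = (box_w + box_h)/4`, half the mean box extent).
Normalized circle errors (center and radius) use the same `(W+H)/2`
denominator, so "2% error" means 2% of the mean image dimension.

## Edge signal

The refinement consumes an `EdgeMap` built from an enhanced ROI crop:

1. CLAHE (scikit-image convention: clip limit 0.01, 8×8 tiles) for local
   contrast;
2. edge-preserving bilateral filtering (window 9 px, σ_color 25 gray levels,
   σ_spatial 3 px);
3. optional unsharp masking (radius 2, amount 1.0, on by default).

Canny hysteresis thresholds adapt to the image through the median gray
level v: `T_low = max(0, (1−σ)v)`, `T_high = min(255, (1+σ)v)` with
σ = 0.33. Because scikit-image's Canny compares thresholds against gradient
magnitudes, the intensity-domain band is mapped onto the gradient scale by
`g_max/255`, preserving the relative operating point. The combined response
is `w_c · canny + w_g · grad/g_max` with default weights (0.5, 0.5); the
gradient term lets stages see edges too faint for hysteresis, the Canny term
anchors crisp boundaries at 0.5+.

## Refinement pipeline

**Femoral head.** Edge-Snap: 360 radial profiles inside an annulus of
half-width 0.2·r around the proposal; per-angle argmax radii pooled by a
weighted median (weights = peak responses, ties to the lower radius —
deterministic and biased toward the inner, joint-space-side edge). Support
is the fraction of angles whose peak clears a noise floor (0.2); below 10%
support the input radius is kept. The center is never moved by Edge-Snap;
center refinement is RANSAC's job: high-response pixels in a thin ring
(half-width 0.15·r, top 30% of positive responses) feed a RANSAC fitter
(500 iterations, inlier tolerance 2 px) whose winner is polished by a
closed-form Kåsa least-squares fit. When C(n,3) ≤ n_iter the triplets are
enumerated exhaustively instead of sampled, making small instances exactly
reproducible and directly comparable to a brute-force oracle.

**Acetabular cup.** The rim is often partially occluded, so the cup gets a
deterministic candidate grid (3×3 center offsets up to 0.08·r, 5 radius
scales in [0.9, 1.15], the proposal always included), per-candidate
Edge-Snap with a tighter annulus (0.1), optional RANSAC polish, and a
six-component composite score, each component in [0, 1]:

- *edge support* — of the strong pixels (combined ≥ 0.25) in a surrounding
  annulus (±3 tolerances), the fraction radially within tolerance
  (max(2 px, 3% r)) of the candidate radius;
- *angular coverage* — fraction of 360 angular bins whose ring peak clears
  the support threshold;
- *longest arc* — longest contiguous supported arc (radians / 2π in the
  composite);
- *gradient alignment* — mean |cos| between gradient direction and the
  radial direction over supported bins (absolute value: rim polarity flips
  between inner and outer edges);
- *center proximity* — 1 − d/(r/2) clamped, d = distance to the ROI center;
- *outside fraction* — fraction of supporting points strictly outside the
  fitted femoral circle (a cup must envelop the head, not cut through it).

The composite is the weighted mean with uniform default weights (1/6 each,
configurable); selection arguments rest on orderings, not absolute totals.

**Anatomical filter.** A candidate pair passes only if: cup radius strictly
exceeds the femoral radius; the head sits strictly inside the cup with at
least `min_gap` = 1 px of joint-space clearance (`r_AC − r_fem − ‖c_AC −
c_fem‖ ≥ min_gap`, a liner-thickness floor); the cup center lies inside the
ROI; and the edge density along each rim band (±2 px) is at least 0.02.
Density counts Canny pixels *or* pixels whose combined response clears 0.1:
on a synthetic rim the adaptive Canny is nearly all-or-nothing, and a
pure-Canny density would declare a coherent but sub-threshold rim "empty" —
exactly the regime the Hough fallback exists for. With default weights
Canny pixels dominate the count wherever Canny fires.

**Hough fallback.** Triggered when the grid's best candidate has composite
total < 0.35 *or* angular coverage < 0.5 (a tangent noise circle can score
~0.6 on proximity/alignment alone while covering a quarter of the rim;
coverage is the direct "insufficient edge support" signal). The circular
Hough transform votes along gradient-direction rays (two centers per pixel
per radius, votes weighted by combined response, 1 px radius bins, greedy
non-maximum suppression). Because the cup rim must lie outside the fitted
femoral circle, only pixels outside it may vote and the radius range starts
above `r_fem + min_gap`; the range is wider than the grid's
(0.6–1.35 × proposal) since a triggered fallback means the proposal itself
is suspect. Hough candidates are snapped, scored and filtered identically
and replace the incumbent only when strictly higher-scoring; the returned
fit records which path won. Finally, a winner whose angular coverage is
still below 0.5 is rejected outright: CLAHE on a blank ROI manufactures
full-contrast noise texture that can satisfy the four filter rules, and
contiguous coverage is what separates a rim from noise.

## Wear computation

With PRE/POST geometries, `d` is the head-to-cup center distance and `g`
the absolute vertical distance between the two superior points. The
absolute value makes `g` independent of which circle tops out higher (the
raw difference is signed and convention-dependent; the derived quantities
are unchanged for a head strictly inside the cup). The femoral-radius
scale factor `sf = r_fem,PRE / r_fem,POST` multiplies the POST measurements,
cancelling any magnification difference exactly — scaling all POST geometry
by k > 0 leaves Δd, Δg, Δtotal invariant, which is both a property test and
the design rationale. Δd and Δg stay signed (negative = the head moved the
other way); Δtotal is their Euclidean norm. PRE is always the reference
scale. The directional sense of "medial" is not recoverable from the
center distance alone and is not asserted. Reports are written as labeled
`key value` text lines at 6-decimal fixed point; millimetre conversion
(Δtotal / M) appears only when a magnification factor is supplied.

## Detection metrics

Greedy one-to-one matching in descending confidence, per class, TP iff IoU
> τ (default 0.5). AP uses all-points (continuous) integration of the PR
curve — a sum of precision × recall-increment over the ranked list — rather
than 11-point interpolation; mAP averages the two classes. P95 uses linear
interpolation between order statistics. These conventions are validated
against exhaustive enumeration oracles in the test suite.

## Phantom generator

The generator emulates what the pipeline actually consumes — edge geometry —
not radiographic physics. A phantom is: uniform background (default gray
40), an anti-aliased bright head disc (+90), and a cup rim with a sharp
inner step at the true cup radius (+80) fading linearly outward over the
rim width (5 px). The one-sided rim makes the strongest rim edge coincide
with the ground-truth circle (the joint-space side a human reader would
trace); a symmetric annulus would leave the "true" radius ambiguous between
two equally strong edges. Degradations: seeded additive Gaussian noise
(clipped to [0, 255]), occluding arcs deleted from the rim (overlapping
bone/hardware), and bright 2-px line segments (screws). Study conditions
for the recovery experiments: 320×320 images, femoral radius 30–44 px,
joint gap 9–16 px, contrasts 60–110 gray levels, noise σ 2–8, up to 60° of
rim occlusion, ROI jitter 3% — 30 phantoms per run, sized so the full
recovery experiment completes in well under a minute while exercising every
degradation the generator models.

What passing these tests does *not* show: performance on clinical
radiographs with bone texture, projection tilt, elliptical rim projection,
contralateral anatomy, or detector failure modes beyond the jittered /
displaced boxes simulated here. The phantoms validate the geometry engine,
not clinical accuracy.

## PRE/POST simulation

`generate_pre_post_pair` translates the femoral center by a chosen shift,
then multiplies *all* POST geometry (circles, rim width, image dimensions)
by a magnification factor. The expected wear report is computed
analytically from the spec circles; by construction the scale factor
cancels the magnification exactly, so a pure-magnification pair has zero
expected wear — a sharp end-to-end test of the sf correction.

## Numerical choices and degenerate inputs

- Three-point circles use the closed-form perpendicular-bisector solution;
  triplets with |2·area| ≤ 1e-9 × squared point spread are degenerate.
- The Kåsa fit is linear least squares on (2cx, 2cy, r²−cx²−cy²); rank
  deficiency (collinear points) raises a geometry error. It is exact on
  noiseless circles and adequate as a RANSAC polish; no iterative geometric
  refinement is attempted.
- RANSAC ties (equal inlier counts) break toward lower mean inlier
  residual; the weighted median breaks ties toward the lower radius.
- All randomness (RANSAC sampling beyond the exhaustive regime, phantom
  noise, ROI jitter) flows from explicit integer seeds; identical inputs
  and seeds give bit-identical fits.
- Images are 8-bit grayscale; multi-channel inputs are reduced by channel
  averaging on load.

## Limitations

- The cup rim is modeled as a circle; real cup openings project as
  ellipses under pelvic tilt. Out of scope by design.
- Laterality is unknown, so "center drifts toward the contralateral hip"
  is enforced only as ROI containment.
- Millimetre calibration requires a user-supplied magnification factor;
  no DICOM pixel-spacing is read.
- The detector itself (training, weights, dataset-level mAP) is outside
  this package; only its output format is consumed.
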