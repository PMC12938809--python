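# hipwear

Hybrid circle detection and 2D polyethylene-wear measurement for
anteroposterior (AP) hip radiographs with total hip arthroplasty (THA).

After THA, the prosthetic femoral head slowly penetrates the polyethylene
liner of the acetabular cup (AC). On serial AP radiographs this wear shows up
as a change in the head–cup geometry, which can be quantified once the two
projected circles — femoral head and cup rim — are known with sub-pixel
accuracy. `hipwear` provides the geometric half of that workflow for
researchers building automated THA surveillance pipelines: it is
detector-agnostic (any object detector, or a ground-truth oracle, may supply
the region of interest) and does everything downstream of the ROI:

- **Edge-Snap refinement** — radial profiles of a combined Canny + gradient
  edge signal are sampled over many angles inside a narrow annulus around a
  coarse circle proposal; per-angle peak radii are pooled by a
  response-weighted median.
- **RANSAC circle fitting** — circles hypothesized from random edge-point
  triplets, scored by inliers (|‖p − c‖ − r| ≤ τ), polished by an algebraic
  least-squares fit.
- **Cup candidate search** — a grid of center shifts and radius scales,
  each candidate snapped, scored by a six-component composite (edge support,
  angular coverage, longest supported arc, gradient/normal alignment, ROI
  proximity, support outside the femoral circle) and screened by anatomical
  constraints (r_AC > r_fem, positive joint-space gap, ROI containment, rim
  edge density).
- **Circular Hough fallback** — gradient-direction voting in a (cx, cy, r)
  accumulator, activated when the candidate grid finds only weakly supported
  circles; its candidates are scored and screened identically and adopted
  only when strictly better.
- **Wear computation** — with PRE/POST circle pairs (c_fem, c_AC, r_fem):

      sf      = r_fem,PRE / r_fem,POST          (magnification cancellation)
      Δd      = d_POST · sf − d_PRE             (medial: center-to-center)
      Δg      = g_POST · sf − g_PRE             (superior: top-point gap)
      Δtotal  = √(Δd² + Δg²)                    (resultant, pixels)
      Wear_mm = Δtotal / M                      (optional magnification M)

- **Evaluation utilities** — IoU, precision/recall/F1, all-points AP and
  mAP, normalized circle-error summaries (Mean ± Std, Median, P95, Max) and
  tolerance–accuracy curves.
- **Phantom generator** — synthetic AP-hip phantoms (bright head disc inside
  a bright cup rim with a joint-space gap, plus noise, occluding arcs and
  screw-like line artifacts) with exact circle ground truth, used as the
  test bed.

## Worked example

```python
from hipwear import wear_from_measurements

report = wear_from_measurements(
    r_fem_pre=126.310866, r_fem_post=123.661418,
    d_pre=4.976189, d_post=10.775240,
    g_pre=73.828397, g_post=73.340661,
)
print(f"sf          {report.sf:.6f}")
print(f"delta_d     {report.delta_d:.6f}")
print(f"delta_g     {report.delta_g:.6f}")
print(f"delta_total {report.delta_total:.6f}")
```

prints

```
sf          1.021425
delta_d     6.029911
delta_g     1.083589
delta_total 6.126499
```

i.e. between the two exams the head migrated 6.03 px medially and 1.08 px
superiorly (in PRE-image pixels, after the scale factor sf removed the
magnification difference), a resultant wear path of 6.13 px.

End-to-end on a synthetic phantom:

```python
from hipwear import PhantomSpec, generate_phantom, fit_prosthesis
from hipwear.roi import oracle_roi_provider

spec = PhantomSpec()                       # 320x320, head r=38, cup r=50
image, truth = generate_phantom(spec)
rois = oracle_roi_provider(truth, spec.dims, jitter=0.03, seed=1)
fit = fit_prosthesis(image, rois)
print(fit.method)                          # "ransac"
print(round(fit.femoral.r, 2), round(fit.cup.r, 2))   # 38.18 50.47
```

## Command line

```sh
hipwear synth 10 data/ --seed 0          # phantom dataset with labels
hipwear detect data/images out/ --truth-dir data/labels_circle --seed 1
hipwear metrics out/ data/labels_circle --width 320 --height 320
hipwear wear pre.txt post.txt --width 640 --height 480 [--magnification M]
```

Exit codes: 0 success, 2 usage, 3 fit failure, 4 parse error. Annotation
files use the normalized text format `cls x y r` (class 0 = femoral head,
1 = cup; x, y fractions of width/height, r a fraction of (W+H)/2).

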