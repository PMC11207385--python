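# Methods

## Measurement model

Head roll is estimated from the two pupil centers only. With image
coordinates (origin top-left, x right, y down, pixel centers on integers)
and the convention that rightward head rotation is positive, a tilt `theta`
raises the right pupil, so the vertical separation `dy = y_left − y_right`
is positive. For a frontal face at distance `z` seen by a pinhole camera of
focal length `f` (pixels),

```
dy_px  = f * ipd_mm * sin(theta) / z
ipd_px = f * ipd_mm / z            =>   dy_px / ipd_px = sin(theta)
```

The calibration is a linear chord fit `theta ≈ a·x + b` with
`x = dy/ipd_px` (default, `measure_kind="normalized_dy"`) or `x = dy` in
raw pixels (`"raw_dy"`, a per-setup fit that changes with distance and
IPD). The normalized fit has slope near `180/π`; its worst-case deviation
from the exact `arcsin` on |theta| ≤ 20° is ≈ 0.35° and the mean deviation
over a 5°-grid sweep is ≈ 0.07°, which bounds the bias the linearization
contributes to the error budget. `geometric_tilt` exposes the arcsin
inverse as an independent oracle. Both measure kinds are first-class
because the role of the regression variables in the original rig is
ambiguous; the normalized form is the default because one model then
serves every distance/IPD combination.

Per video, `dy` is mapped to degrees using the *median* Euclidean pupil
distance over valid frames as `ipd_px` (robust to single-frame fit noise),
the mean tilt of a designated 0° video is subtracted (baseline zeroing:
subjects' eyes are not perfectly level at the reference posture), and the
mean/SD over valid frames summarize the video. Frames with fewer than two
valid pupils carry no angle. Alert events fire once per excursion when
|corrected tilt| exceeds a threshold for at least `debounce_frames`
consecutive valid frames (default 5, ≈ 0.5 s at a 10 Hz analysis rate).
A `mirror` flag flips the dy sign for selfie-view (horizontally mirrored)
capture.

## Synthetic rig

The renderer replaces a physical goniometer/chin-rest/rangefinder setup.
It is a zero-distortion pinhole camera (default 1280×720, f = 1000 px,
principal point at the image center — a 65 mm IPD at 500 mm spans ≈ 130 px,
comparable to a 720p laptop webcam). Head tilt is a pure in-plane rotation
about the inter-pupil midpoint; pitch and yaw are not modeled, matching
the measurement target (lateral tilt only). Two scene types:

* **Templates** — two dark filled circles (default radius 5 mm; the
  physical template's circle size is not critical and is exposed as a
  parameter) on a light background, at IPD 45–85 mm, distance 235–800 mm,
  tilt up to ±25°.
* **Eye frames** — per eye a bright sclera ellipse (semi-axes 2.4/1.5 iris
  radii), an iris disk (default intensity 70) with a concentric darker
  pupil (intensity 20), and a small specular highlight (radius 2 px,
  intensity 250, default offset (3, −2) px from the pupil center), on a
  skin-toned background (140). Iris radius defaults to 5.9 mm (human
  average ≈ 11.8 mm diameter), pupil 2 mm.

Edges are anti-aliased by 4× supersampling so the recorded sub-pixel truth
is meaningful. Additive Gaussian noise is seeded; rendering is a pure
function of (parameters, seed), and sequences derive one sub-seed per
frame. What the renderer deliberately does *not* model: eyelids/blinks,
eyelashes, glasses glare, skin texture, illumination gradients, head
pitch/yaw and perspective foreshortening of a real face. Passing recovery
tests therefore demonstrates the correctness and numerical behavior of the
measurement chain, not its robustness to real-world appearance variation —
on real imagery the pluggable cascade eye-pair detector and parameter
retuning would carry that load.

## Detection chain

1. **Eye-pair box.** The detector backend is pluggable (a Viola–Jones-style
   cascade can be wrapped on real images; none ships). The default finds
   dark compact blobs (threshold halfway between frame minimum and median,
   connected components filtered for area, fill ratio ≥ 0.4 and plausible
   equivalent radius), picks the darkest roughly-horizontal pair
   (|Δy| ≤ 0.6·separation), and pads the joint bounding box by 40% of the
   blob separation to leave context for the iris search.
2. **Split.** The box is halved left/right (odd widths give the left half
   the smaller part); ROI boxes carry their frame offsets so fits map back
   exactly. "Left/right" are image-space terms, not anatomical sides.
3. **Iris localization.** The integrodifferential operator: contour means
   over `angular_samples = 64` bilinear-interpolated points, radial
   finite-difference derivative, 1-D Gaussian smoothing of scale `sigma`,
   maximized over center and radius. Radius bounds come from the pair-box
   height. The pipeline's default fractions are (0.05, 0.22) of box height
   because the padded blob box is tall relative to the iris;
   `radius_bounds_from_box` itself defaults to (0.15, 0.45), which suits
   tighter cascade-style eye-pair boxes. Bounds clamp at 3 px.
4. **Tracking.** Translational pyramidal Lucas–Kanade (patch half-size 10,
   3 levels, ≤ 30 iterations, convergence 0.01 px). A point is lost on
   divergence or RMS residual > 20 intensity units; loss triggers
   re-detection on the same frame, and a failed re-detection yields a gap,
   never an abort.

## Numerical choices

* `sigma = 1.0` px and `radius_step = 0.5` px. Coarser settings
  (σ = 1.5, step 1) proved unsafe for small irises (~8 px at 70 cm): the
  smoothing spread the sharp true boundary enough that off-center circles
  grazing the iris/sclera edge tangentially could out-score it, producing
  multi-degree tilt errors. The finer grid resolves the sharp edge, whose
  response then dominates the broad tangential artifact.
* Contour samples outside the ROI are masked (Daugman's occlusion
  handling); > 50% masked invalidates the radius, and fewer than 3 valid
  radii invalidates the center. Samples inside a 2-px-dilated saturation
  mask (intensity ≥ 245) are also masked: without the dilation the
  partially bright rim of a specular highlight fakes a radial edge.
* The coarse center search is restricted to dark pixels decimated on a
  grid anchored to the dark region (keeping the search
  translation-covariant); the top 5 spatially distinct candidates are
  refined at 1 px, then the winner sub-pixel-refined by a least-squares
  paraboloid on the 3×3 response surface at the winning radius
  (dy resolution directly limits tilt resolution, ≈ 0.4°/px at 500 mm).
  Ties break deterministically: larger response, then smaller radius,
  smaller y, smaller x. The maximized quantity is the *absolute* smoothed
  derivative so inverted polarities are tolerated.
* Template circles are found by a circular Hough transform (Sobel
  gradient-magnitude edges thresholded at 30% of max, accumulator over an
  integer radius range, two highest non-overlapping peaks) and refined to
  sub-pixel by the squared-vote centroid of the (r ± 1) × 5 × 5 peak
  neighborhood. A Hough route is *not* used for irises: at long distances
  the small, lower-contrast iris makes it unreliable, and the operator
  above is both more accurate and cheaper in this regime.
* The specular reflex is the brightest connected region inside the iris
  circle shrunk by a 1.5 px rim margin (the anti-aliased limbus would
  otherwise qualify), thresholded at the 95th percentile of the disk and
  at median + 30; its absence is a non-fatal signal.

## Experiment sizes

The calibration experiments render the full study grid: 6 distances
(235–700 mm) × 9 tilts (0, ±5, ±10, ±15, ±20°) × 3 IPDs (45/65/85 mm),
fitted on a single-setup sweep at 500 mm / 65 mm and evaluated on all 162
held-out images. The end-to-end eye-scene recovery uses IPD {55, 65, 75} mm
× distance {300, 500, 700} mm × tilt {0, 5, 10, 15}° with short static
sequences (4–5 frames each; the per-frame chain is deterministic at zero
noise, so longer videos add little information), and Monte-Carlo noise
properties use 30–50 seeds on a 96×96 single-eye ROI.

## Known limitations

* The blob-pair detector assumes the irises are among the darkest compact
  structures in the frame; dark hair, frames of glasses or deep shadows
  would defeat it on real imagery (use the cascade plug-in there).
* Iris and pupil are treated as concentric; the optional inner-boundary
  pass (`locate_pupil`) exists but the pipeline does not use it.
* Viewing distance is not estimated; the normalized calibration sidesteps
  it for tilt, but absolute-distance features are out of scope.
* Throughput targets (real-time capture) are out of scope; the pipeline is
  offline/batch.
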