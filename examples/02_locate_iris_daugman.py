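"""Locate both irises in one frame with the integrodifferential operator.

Runs the full detection chain — eye-pair box, left/right split, operator
search with box-adaptive radii — and compares the fitted centers with the
renderer's ground truth.
"""

import math

from ocutilt import (
    CameraModel,
    DaugmanParams,
    PipelineConfig,
    detect_eye_pair,
    locate_iris,
    locate_specular_reflex,
    make_eye_scene,
    radius_bounds_from_box,
    render_eye_frame,
    split_eye_region,
)
from ocutilt.detect import crop

camera = CameraModel()
scene = make_eye_scene(camera, ipd_mm=65.0, distance_mm=500.0, tilt_deg=8.0)
frame, _ = render_eye_frame(camera, scene)

box = detect_eye_pair(frame)
print("eye-pair box:", box)
regions = split_eye_region(frame, box)
rmin, rmax = radius_bounds_from_box(box, PipelineConfig().radius_fractions)
params = DaugmanParams(rmin=rmin, rmax=rmax)
print(f"radius search range: {rmin:.1f}..{rmax:.1f} px (true iris {scene.iris_radius_px:.1f} px)")

for name, roi_box, truth in (
    ("left", regions.left_roi, scene.left_pupil_px),
    ("right", regions.right_roi, scene.right_pupil_px),
):
    roi = crop(frame, roi_box)
    fit = locate_iris(roi, params)
    fx, fy = roi_box.to_frame((fit.x, fit.y))
    err = math.hypot(fx - truth[0], fy - truth[1])
    reflex = locate_specular_reflex(roi, fit)
    print(
        f"{name:5s} center ({fx:7.2f}, {fy:7.2f})  radius {fit.radius:5.2f} px  "
        f"center error {err:.3f} px  specular reflex at {reflex}"
    )
print("errors of a few hundredths of a pixel translate to <0.1 deg of tilt")
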