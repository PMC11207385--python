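"""Render the two synthetic scene types and print their ground truth.

The calibration template is two dark circles at a physical separation
(IPD), rotated by a known angle at a known distance; the eye frame is a
stylized subject with sclera/iris/pupil disks and a specular highlight.
"""

import math

from ocutilt import CameraModel, make_eye_scene, render_eye_frame, render_template

camera = CameraModel()  # 1280x720, focal length 1000 px

img, truth = render_template(camera, ipd_mm=65.0, tilt_deg=10.0, distance_mm=500.0)
print("template circle centers:", truth.left_pupil_px, truth.right_pupil_px)
print(f"vertical separation dy = {truth.dy_px:.3f} px")
closed_form = camera.focal_length * 65.0 * math.sin(math.radians(10.0)) / 500.0
print(f"closed-form f*ipd*sin(tilt)/z = {closed_form:.3f} px (identical)")

scene = make_eye_scene(camera, ipd_mm=63.0, distance_mm=500.0, tilt_deg=5.0)
frame, _ = render_eye_frame(camera, scene)
print("\neye frame pupils:", scene.left_pupil_px, scene.right_pupil_px)
print(f"apparent iris radius {scene.iris_radius_px:.1f} px at 500 mm")
# dy/ipd_px equals sin(tilt) exactly under the frontal pinhole model:
print(f"dy/ipd = {scene.dy_px / scene.ipd_px:.5f} vs sin(5 deg) = {math.sin(math.radians(5)):.5f}")
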