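"""Fit the tilt calibration from a rendered goniometer sweep.

Templates are rendered at -20..+20 degrees, the two circles are found with
the Hough transform, and tilt degrees are regressed on the normalized
vertical separation dy/ipd_px.  The slope lands near 180/pi because
dy/ipd = sin(tilt) for frontal geometry.
"""

from ocutilt import calibrate_from_sweep, geometric_tilt, apply_calibration

model = calibrate_from_sweep(distance_mm=500.0, ipd_mm=65.0)
print(f"degrees = {model.slope:.3f} * (dy/ipd) + {model.intercept:+.4f}")
print(f"Pearson R = {model.pearson_r:.5f} over {model.n_points} angles")
print(f"residual SD = {model.residual_sd:.3f} deg")

dy, ipd = 22.6, 130.0  # a plausible measurement at 500 mm
print(f"\nexample: dy={dy} px, ipd={ipd} px")
print(f"  linear calibration: {apply_calibration(model, dy, ipd):.3f} deg")
print(f"  exact arcsin oracle: {geometric_tilt(dy, ipd):.3f} deg")
print("the chord fit stays within ~0.35 deg of arcsin on |tilt| <= 20 deg")
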