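"""Synthetic recovery experiments.

These drive the renderer, the detectors and the calibration end to end and
score them against ground truth — the package's stand-in for a physical
goniometer rig and for subject studies.  Default grids mirror the study
conditions: six template distances from 23.5 to 70 cm, tilts 0 to +-20
degrees in 5-degree steps, and interpupillary distances spanning 45-85 mm.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import calibration as cal
from .calibration import CalibrationModel
from .errors import DetectionFailure
from .pipeline import PipelineConfig, estimate_baseline, measure_frames, summarize
from .scene import CameraModel, EyeStyle, make_eye_scene, render_sequence, render_template

__all__ = [
    "TEMPLATE_DISTANCES_MM",
    "TEMPLATE_TILTS_DEG",
    "TEMPLATE_IPDS_MM",
    "calibrate_from_sweep",
    "template_sweep_errors",
    "run_recovery_experiment",
]

# Study conditions of the calibration rig.
TEMPLATE_DISTANCES_MM = (235.0, 330.0, 425.0, 520.0, 610.0, 700.0)
TEMPLATE_TILTS_DEG = (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0)
TEMPLATE_IPDS_MM = (45.0, 65.0, 85.0)


def calibrate_from_sweep(
    camera: CameraModel | None = None,
    distance_mm: float = 500.0,
    ipd_mm: float = 65.0,
    tilts_deg: tuple[float, ...] = TEMPLATE_TILTS_DEG,
    measure_kind: str = "normalized_dy",
    circle_radius_mm: float = 5.0,
) -> CalibrationModel:
    """Fit the degree<->pixel-measure line from one rendered template sweep."""
    camera = camera or CameraModel()
    observations = []
    for tilt in tilts_deg:
        img, _ = render_template(camera, ipd_mm, tilt, distance_mm, circle_radius_mm)
        observations.append(
            cal.observe_template(img, tilt, distance_mm=distance_mm, ipd_mm=ipd_mm)
        )
    return cal.fit_calibration(observations, measure_kind=measure_kind)


def template_sweep_errors(
    model: CalibrationModel,
    camera: CameraModel | None = None,
    distances_mm: tuple[float, ...] = TEMPLATE_DISTANCES_MM,
    tilts_deg: tuple[float, ...] = TEMPLATE_TILTS_DEG,
    ipds_mm: tuple[float, ...] = TEMPLATE_IPDS_MM,
    circle_radius_mm: float = 5.0,
) -> pd.DataFrame:
    """Predict tilt on a held-out template grid and score against truth.

    Each grid cell renders a fresh template, detects both circles with the
    Hough transform, applies the calibration and records the absolute error
    in degrees.
    """
    camera = camera or CameraModel()
    rows = []
    for distance in distances_mm:
        for ipd in ipds_mm:
            for tilt in tilts_deg:
                img, truth = render_template(camera, ipd, tilt, distance, circle_radius_mm)
                left, right = cal.detect_template_circles(img)
                dy = cal.pixel_dy(left.center, right.center)
                ipd_px = math.hypot(right.x - left.x, right.y - left.y)
                pred = cal.apply_calibration(model, dy, ipd_px)
                rows.append(
                    {
                        "distance_mm": distance,
                        "ipd_mm": ipd,
                        "tilt_deg": tilt,
                        "dy_px": dy,
                        "ipd_px": ipd_px,
                        "predicted_deg": pred,
                        "abs_error_deg": abs(pred - tilt),
                    }
                )
    return pd.DataFrame(rows)


def run_recovery_experiment(
    model: CalibrationModel,
    camera: CameraModel | None = None,
    ipds_mm: tuple[float, ...] = (55.0, 65.0, 75.0),
    distances_mm: tuple[float, ...] = (300.0, 500.0, 700.0),
    tilts_deg: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0),
    n_frames: int = 5,
    noise_sd: float = 0.0,
    ocular_offset_deg: float = 0.0,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """End-to-end tilt recovery on rendered subject sequences.

    For each (IPD, distance) a 0-degree sequence estimates the baseline
    (absorbing any built-in ocular misalignment ``ocular_offset_deg``);
    each device tilt is then measured from a fresh sequence and compared
    with the commanded tilt.
    """
    camera = camera or CameraModel()
    config = config or PipelineConfig()
    rows = []
    for i_ipd, ipd in enumerate(ipds_mm):
        for i_d, distance in enumerate(distances_mm):
            base_scene = make_eye_scene(
                camera, ipd_mm=ipd, distance_mm=distance, tilt_deg=ocular_offset_deg
            )
            style = EyeStyle(noise_sd=noise_sd, seed=(seed * 9176 + i_ipd * 31 + i_d) % (2**31))
            base_frames = [f for f, _ in render_sequence(camera, [base_scene] * n_frames, style)]
            try:
                baseline = estimate_baseline(measure_frames(base_frames, model, config))
            except Exception:
                baseline = 0.0
            for tilt in tilts_deg:
                scene = make_eye_scene(
                    camera,
                    ipd_mm=ipd,
                    distance_mm=distance,
                    tilt_deg=tilt + ocular_offset_deg,
                )
                frames = [f for f, _ in render_sequence(camera, [scene] * n_frames, style)]
                import dataclasses as _dc

                cfg = _dc.replace(config, baseline_offset_deg=baseline)
                summary = summarize(measure_frames(frames, model, cfg))
                measured = summary.mean_tilt_deg
                rows.append(
                    {
                        "ipd_mm": ipd,
                        "distance_mm": distance,
                        "tilt_deg": tilt,
                        "measured_deg": measured,
                        "abs_error_deg": abs(measured - tilt),
                        "fraction_valid": summary.fraction_valid,
                    }
                )
    return pd.DataFrame(rows)
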