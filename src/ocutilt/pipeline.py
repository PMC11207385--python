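"""End-to-end head-tilt measurement.

Per frame: detect the eye-pair region, split it, localize each iris with the
integrodifferential operator (or track the pupil centers from the previous
frame), compute the vertical pixel separation dy of the two centers, and map
it to degrees through the fitted calibration.  Per video: subtract the tilt
measured at the device's 0-degree position (subjects' eyes are rarely
perfectly level), average the per-frame tilts, and emit alert events when
the corrected tilt stays beyond a threshold for a debounce interval.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import daugman, detect, tracking
from .calibration import CalibrationModel, apply_calibration
from .errors import BaselineUnavailableError, ConfigError, DetectionFailure
from .tracking import PupilPair, TrackerConfig

__all__ = [
    "PipelineConfig",
    "TiltSample",
    "TiltSummary",
    "AlertEvent",
    "detect_pupil_pair",
    "measure_frames",
    "estimate_baseline",
    "apply_baseline",
    "summarize",
    "check_alerts",
    "samples_to_dataframe",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the measurement chain in one place.

    ``radius_fractions`` scale the iris radius search to the eye-pair box
    height; the default suits the blob-pair detector's padded boxes, where
    the iris radius is a small fraction of the box (cascade-style boxes
    need larger fractions).  ``mirror`` flips the dy sign for mirrored
    (selfie-view) capture.
    """

    radius_fractions: tuple[float, float] = (0.05, 0.22)
    daugman_sigma: float = 1.0
    radius_step: float = 0.5
    angular_samples: int = 64
    min_response: float = 5.0
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    baseline_offset_deg: float = 0.0
    alert_threshold_deg: float = 10.0
    debounce_frames: int = 5
    mirror: bool = False


@dataclass(frozen=True)
class TiltSample:
    """Per-frame tilt; invalid samples carry NaN geometry and no angles."""

    frame_index: int
    dy_px: float
    ipd_px: float
    tilt_raw_deg: float
    tilt_corrected_deg: float
    valid: bool
    source: str = "detected"

    @classmethod
    def invalid(cls, frame_index: int) -> "TiltSample":
        nan = float("nan")
        return cls(frame_index, nan, nan, nan, nan, False)


@dataclass(frozen=True)
class TiltSummary:
    """Per-video aggregate over valid, baseline-corrected samples."""

    n_frames_used: int
    mean_tilt_deg: float
    sd_tilt_deg: float
    fraction_valid: float


@dataclass(frozen=True)
class AlertEvent:
    frame_index: int
    tilt_deg: float
    threshold_deg: float
    message: str

    def __post_init__(self) -> None:
        if not abs(self.tilt_deg) > self.threshold_deg:
            raise ConfigError("alert tilt must exceed the threshold")


def detect_pupil_pair(
    frame: np.ndarray, config: PipelineConfig = PipelineConfig()
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Full detection chain on one frame: pair box -> split -> iris fits.

    Returns the two pupil centers in full-frame coordinates (left, right).
    Raises :class:`DetectionFailure` when any stage finds nothing.
    """
    box = detect.detect_eye_pair(frame)
    regions = detect.split_eye_region(frame, box)
    rmin, rmax = daugman.radius_bounds_from_box(box, config.radius_fractions)
    params = daugman.DaugmanParams(
        rmin=rmin,
        rmax=rmax,
        sigma=config.daugman_sigma,
        radius_step=config.radius_step,
        angular_samples=config.angular_samples,
    )
    centers = []
    for roi_box in (regions.left_roi, regions.right_roi):
        roi = detect.crop(frame, roi_box)
        fit = daugman.locate_iris(roi, params, min_response=config.min_response)
        centers.append(roi_box.to_frame((fit.x, fit.y)))
    return centers[0], centers[1]


def _pair_geometry(pair: PupilPair, mirror: bool) -> tuple[float, float]:
    dy = pair.left[1] - pair.right[1]
    if mirror:
        dy = -dy
    ipd = math.hypot(pair.right[0] - pair.left[0], pair.right[1] - pair.left[1])
    return dy, ipd


def measure_frames(
    frames: Sequence[np.ndarray],
    calibration: CalibrationModel,
    config: PipelineConfig = PipelineConfig(),
) -> list[TiltSample]:
    """Per-frame tilt for a whole sequence.

    Frames where either pupil is missing yield invalid samples.  For the
    normalized calibration the per-video scale is the median Euclidean
    pupil distance over valid frames, which is robust to single-frame fit
    noise.  ``config.baseline_offset_deg`` is subtracted from every raw
    tilt (zero until a baseline has been estimated).
    """
    pairs = tracking.track_with_reacquisition(
        frames, lambda f: detect_pupil_pair(f, config), config.tracker
    )
    geoms = {
        p.frame_index: _pair_geometry(p, config.mirror) for p in pairs if p.both_valid
    }
    if not geoms:
        warnings.warn("no frame yielded a valid pupil pair", stacklevel=2)
        return [TiltSample.invalid(p.frame_index) for p in pairs]
    ipd_video = float(np.median([g[1] for g in geoms.values()]))
    samples = []
    for p in pairs:
        if not p.both_valid:
            samples.append(TiltSample.invalid(p.frame_index))
            continue
        dy, ipd = geoms[p.frame_index]
        try:
            raw = apply_calibration(calibration, dy, ipd_video)
        except Exception:
            samples.append(TiltSample.invalid(p.frame_index))
            continue
        samples.append(
            TiltSample(
                frame_index=p.frame_index,
                dy_px=dy,
                ipd_px=ipd,
                tilt_raw_deg=raw,
                tilt_corrected_deg=raw - config.baseline_offset_deg,
                valid=True,
                source=p.source,
            )
        )
    return samples


def estimate_baseline(samples: Sequence[TiltSample]) -> float:
    """Mean raw tilt of the designated 0-degree video.

    The result is subtracted from subsequent measurements to compensate for
    eyes that are not perfectly level at the reference posture.
    """
    raws = [s.tilt_raw_deg for s in samples if s.valid]
    if not raws:
        raise BaselineUnavailableError("no valid samples to estimate a baseline from")
    return float(np.mean(raws))


def apply_baseline(samples: Sequence[TiltSample], baseline_deg: float) -> list[TiltSample]:
    """Re-derive corrected tilts from raw tilts with the given baseline."""
    out = []
    for s in samples:
        if s.valid:
            out.append(
                dataclasses.replace(s, tilt_corrected_deg=s.tilt_raw_deg - baseline_deg)
            )
        else:
            out.append(s)
    return out


def summarize(samples: Sequence[TiltSample]) -> TiltSummary:
    """Mean/SD of corrected tilt over valid samples; empty input is a
    zero-count summary, not an error."""
    vals = np.array([s.tilt_corrected_deg for s in samples if s.valid])
    n_total = len(samples)
    if vals.size == 0:
        return TiltSummary(0, float("nan"), float("nan"), 0.0)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return TiltSummary(
        n_frames_used=int(vals.size),
        mean_tilt_deg=float(np.mean(vals)),
        sd_tilt_deg=sd,
        fraction_valid=vals.size / n_total if n_total else 0.0,
    )


def check_alerts(
    samples: Sequence[TiltSample],
    threshold_deg: float = 10.0,
    debounce_frames: int = 5,
) -> list[AlertEvent]:
    """One event per excursion of |corrected tilt| beyond the threshold.

    An excursion qualifies when it lasts at least ``debounce_frames``
    consecutive valid frames; the event is stamped with the first frame of
    the qualifying run.  (Audio playback is out of scope: alerts are
    structured events for the caller's log stream.)
    """
    if threshold_deg <= 0:
        raise ConfigError("threshold_deg must be positive")
    if debounce_frames < 1:
        raise ConfigError("debounce_frames must be >= 1")
    events: list[AlertEvent] = []
    run: list[TiltSample] = []

    def flush(run: list[TiltSample]) -> None:
        if len(run) >= debounce_frames:
            first = run[0]
            events.append(
                AlertEvent(
                    frame_index=first.frame_index,
                    tilt_deg=first.tilt_corrected_deg,
                    threshold_deg=threshold_deg,
                    message=(
                        f"head tilt {first.tilt_corrected_deg:+.1f} deg exceeds "
                        f"threshold {threshold_deg:.1f} deg"
                    ),
                )
            )

    for s in samples:
        if s.valid and abs(s.tilt_corrected_deg) > threshold_deg:
            run.append(s)
        else:
            flush(run)
            run = []
    flush(run)
    return events


def samples_to_dataframe(samples: Sequence[TiltSample]) -> pd.DataFrame:
    """Tabular per-frame output (one row per frame, invalid rows NaN)."""
    return pd.DataFrame([dataclasses.asdict(s) for s in samples])
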