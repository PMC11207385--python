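"""Pupil-center tracking across frames.

A translational Kanade-Lucas-Tomasi tracker follows the two pupil centers:
for each point a small intensity patch is aligned to the next frame by
iterative least squares on a Gaussian image pyramid.  Only translation is
estimated — pupil patches are small and the measured head motion is
near-planar, so an affine warp buys nothing.

A point is declared lost when its alignment diverges or its final residual
exceeds a threshold (the observable proxies for illumination change or loss
of fixation); :func:`track_with_reacquisition` then re-runs the full
detection chain on that frame and re-initializes, so a single bad frame
costs one sample, never the sequence.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import ConfigError, DetectionFailure, InvalidGeometryError

__all__ = [
    "PupilPair",
    "TrackerConfig",
    "TrackerState",
    "init_tracker",
    "track",
    "track_with_reacquisition",
]


@dataclass(frozen=True)
class PupilPair:
    """Left/right pupil centers for one frame, in full-frame coordinates.

    "Left"/"right" are image-space sides; when both points are valid the
    right center has the larger x.
    """

    frame_index: int
    left: tuple[float, float] | None
    right: tuple[float, float] | None
    left_valid: bool
    right_valid: bool
    source: str  # "detected" | "tracked"

    def __post_init__(self) -> None:
        if self.source not in ("detected", "tracked"):
            raise ConfigError("source must be 'detected' or 'tracked'")
        if self.left_valid and self.right_valid:
            if self.right[0] <= self.left[0]:
                raise InvalidGeometryError("right pupil must lie right of the left")

    @classmethod
    def ordered(
        cls,
        frame_index: int,
        a: tuple[float, float],
        b: tuple[float, float],
        source: str,
    ) -> "PupilPair":
        """Build a fully valid pair, assigning left/right by x."""
        left, right = sorted((tuple(a), tuple(b)), key=lambda p: p[0])
        return cls(frame_index, left, right, True, True, source)

    @classmethod
    def invalid(cls, frame_index: int) -> "PupilPair":
        return cls(frame_index, None, None, False, False, "detected")

    @property
    def both_valid(self) -> bool:
        return self.left_valid and self.right_valid


@dataclass(frozen=True)
class TrackerConfig:
    patch_half_size: int = 10
    pyramid_levels: int = 3
    max_iterations: int = 30
    convergence_tol: float = 0.01  # px
    max_residual: float = 20.0  # RMS intensity units

    def __post_init__(self) -> None:
        if self.patch_half_size < 1 or self.pyramid_levels < 1:
            raise ConfigError("patch_half_size and pyramid_levels must be >= 1")
        if self.max_iterations < 1 or self.convergence_tol <= 0 or self.max_residual <= 0:
            raise ConfigError("invalid tracker thresholds")


@dataclass
class TrackerState:
    """Template patches and point positions carried between frames."""

    config: TrackerConfig
    frame_shape: tuple[int, int]
    points: list[np.ndarray]  # [left, right], each (x, y)
    templates: list[list[np.ndarray]]  # per point, per pyramid level
    lost_count: list[int] = field(default_factory=lambda: [0, 0])


def _pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(frame, dtype=float)]
    for _ in range(levels - 1):
        pyr.append(gaussian_filter(pyr[-1], 1.0)[::2, ::2])
    return pyr


def _sample_patch(img: np.ndarray, x: float, y: float, half: int) -> np.ndarray:
    offs = np.arange(-half, half + 1, dtype=float)
    ys = y + offs[:, None] + np.zeros_like(offs)[None, :]
    xs = x + offs[None, :] + np.zeros_like(offs)[:, None]
    return map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _point_fits(shape: tuple[int, int], x: float, y: float, half: int, levels: int) -> bool:
    for lvl in range(levels):
        s = 2**lvl
        hl, wl = (shape[0] - 1) // s + 1, (shape[1] - 1) // s + 1
        xl, yl = x / s, y / s
        if not (half <= xl <= wl - 1 - half and half <= yl <= hl - 1 - half):
            return False
    return True


def init_tracker(frame: np.ndarray, pair: PupilPair, config: TrackerConfig = TrackerConfig()) -> TrackerState:
    """Store template patches around both pupil centers.

    Both points must be valid and far enough from the frame border for the
    patch to fit at every pyramid level.
    """
    if not pair.both_valid:
        raise ConfigError("tracker initialization needs both pupils valid")
    frame = np.asarray(frame, dtype=float)
    half = config.patch_half_size
    for x, y in (pair.left, pair.right):
        if not _point_fits(frame.shape, x, y, half, config.pyramid_levels):
            raise InvalidGeometryError("pupil too near the frame border for the patch")
    pyr = _pyramid(frame, config.pyramid_levels)
    points = [np.array(pair.left, dtype=float), np.array(pair.right, dtype=float)]
    templates = [
        [_sample_patch(pyr[lvl], p[0] / 2**lvl, p[1] / 2**lvl, half) for lvl in range(config.pyramid_levels)]
        for p in points
    ]
    return TrackerState(config=config, frame_shape=frame.shape, points=points, templates=templates)


def _track_point(
    pyr: list[np.ndarray],
    grads: list[tuple[np.ndarray, np.ndarray]],
    point: np.ndarray,
    templates: list[np.ndarray],
    config: TrackerConfig,
) -> tuple[np.ndarray | None, float]:
    """Pyramidal translational alignment of one patch.

    Returns (displacement, rms_residual) or (None, inf) on divergence.
    """
    half = config.patch_half_size
    d = np.zeros(2)
    for lvl in reversed(range(len(pyr))):
        s = 2**lvl
        img = pyr[lvl]
        gy, gx = grads[lvl]
        px, py = point[0] / s, point[1] / s
        dl = d / s
        tmpl = templates[lvl]
        hl, wl = img.shape
        for _ in range(config.max_iterations):
            cx, cy = px + dl[0], py + dl[1]
            if not (half - 1 <= cx <= wl - half and half - 1 <= cy <= hl - half):
                return None, math.inf
            patch = _sample_patch(img, cx, cy, half)
            err = patch - tmpl
            Gx = _sample_patch(gx, cx, cy, half)
            Gy = _sample_patch(gy, cx, cy, half)
            H = np.array(
                [[np.sum(Gx * Gx), np.sum(Gx * Gy)], [np.sum(Gx * Gy), np.sum(Gy * Gy)]]
            )
            b = -np.array([np.sum(Gx * err), np.sum(Gy * err)])
            if abs(np.linalg.det(H)) < 1e-12:
                return None, math.inf
            step = np.linalg.solve(H, b)
            dl = dl + step
            if np.hypot(*step) < config.convergence_tol:
                break
        d = dl * s
        if np.hypot(*d) > 4 * half * 2 ** (len(pyr) - 1):
            return None, math.inf
    cx, cy = point[0] + d[0], point[1] + d[1]
    patch = _sample_patch(pyr[0], cx, cy, half)
    rms = float(np.sqrt(np.mean((patch - templates[0]) ** 2)))
    return d, rms


def track(state: TrackerState, frame: np.ndarray) -> tuple[PupilPair, TrackerState]:
    """Advance both points to ``frame``; valid points update the state.

    A point whose residual exceeds ``max_residual`` or whose iteration
    diverges is flagged invalid; its template and position are left
    untouched so a later re-acquisition decides what to do.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != state.frame_shape:
        raise ConfigError("frame size differs from the tracker's reference")
    cfg = state.config
    pyr = _pyramid(frame, cfg.pyramid_levels)
    grads = []
    for img in pyr:
        gy, gx = np.gradient(img)
        grads.append((gy, gx))
    new_points: list[np.ndarray | None] = [None, None]
    valid = [False, False]
    for i in range(2):
        d, rms = _track_point(pyr, grads, state.points[i], state.templates[i], cfg)
        if d is None or rms > cfg.max_residual:
            state.lost_count[i] += 1
            continue
        p = state.points[i] + d
        if not _point_fits(state.frame_shape, p[0], p[1], cfg.patch_half_size, cfg.pyramid_levels):
            state.lost_count[i] += 1
            continue
        new_points[i] = p
        valid[i] = True
    if all(valid) and new_points[1][0] <= new_points[0][0]:
        valid = [False, False]  # crossed points: tracking is nonsense
    for i in range(2):
        if valid[i]:
            state.points[i] = new_points[i]
            state.templates[i] = [
                _sample_patch(pyr[lvl], new_points[i][0] / 2**lvl, new_points[i][1] / 2**lvl, cfg.patch_half_size)
                for lvl in range(cfg.pyramid_levels)
            ]
            state.lost_count[i] = 0
    pair = PupilPair(
        frame_index=-1,
        left=tuple(new_points[0]) if valid[0] else None,
        right=tuple(new_points[1]) if valid[1] else None,
        left_valid=valid[0],
        right_valid=valid[1],
        source="tracked",
    )
    return pair, state


PupilDetector = Callable[[np.ndarray], tuple[tuple[float, float], tuple[float, float]]]


def track_with_reacquisition(
    frames: Sequence[np.ndarray],
    detector_chain: PupilDetector,
    config: TrackerConfig = TrackerConfig(),
) -> list[PupilPair]:
    """Track both pupils through a sequence, re-detecting on loss.

    ``detector_chain`` runs the full detection chain (eye-pair box, split,
    iris localization) on one frame and returns the two pupil centers,
    raising :class:`DetectionFailure` when it cannot.  Whenever either
    point is invalid the chain is re-run on that same frame; if that also
    fails the frame yields an all-invalid pair (a gap, not an abort).  The
    output always has one :class:`PupilPair` per input frame.
    """
    if len(frames) == 0:
        raise ConfigError("empty frame sequence")
    results: list[PupilPair] = []
    state: TrackerState | None = None
    for i, frame in enumerate(frames):
        pair: PupilPair | None = None
        if state is not None:
            tracked, state = track(state, frame)
            tracked = dataclasses.replace(tracked, frame_index=i)
            if tracked.both_valid:
                pair = tracked
            else:
                state = None
        if pair is None:
            try:
                a, b = detector_chain(frame)
                pair = PupilPair.ordered(i, a, b, "detected")
                state = init_tracker(frame, pair, config)
            except (DetectionFailure, InvalidGeometryError):
                pair = PupilPair.invalid(i)
                state = None
        results.append(pair)
    return results
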