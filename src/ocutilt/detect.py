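"""Eye-pair region detection and left/right splitting.

The detector backend is pluggable: any callable mapping a frame to a list of
``(BoundingBox, score)`` candidates can stand in (e.g. a Viola-Jones cascade
wrapper on real imagery).  The shipped default, :func:`detect_blob_pair`,
finds the two darkest compact blobs of plausible size — the iris/pupil
disks — and returns their joint bounding box padded with context for the
iris search.

"Left" and "right" are image-space terms (viewer's perspective) throughout,
not the subject's anatomical sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage import measure

from .errors import DetectionFailure, InvalidGeometryError

__all__ = [
    "BoundingBox",
    "EyeRegions",
    "BlobPairConfig",
    "detect_blob_pair",
    "detect_eye_pair",
    "split_eye_region",
    "crop",
]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned pixel box [x, x+width) x [y, y+height)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidGeometryError("bounding box must have positive size")

    @property
    def right(self) -> int:
        return self.x + self.width

    @property
    def bottom(self) -> int:
        return self.y + self.height

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.right and self.y <= py < self.bottom

    def to_frame(self, roi_xy: tuple[float, float]) -> tuple[float, float]:
        """Map ROI coordinates back into full-frame coordinates."""
        return (roi_xy[0] + self.x, roi_xy[1] + self.y)

    def to_roi(self, frame_xy: tuple[float, float]) -> tuple[float, float]:
        """Map full-frame coordinates into this box's ROI coordinates."""
        return (frame_xy[0] - self.x, frame_xy[1] - self.y)


@dataclass(frozen=True)
class EyeRegions:
    """An eye-pair box split into its left and right halves."""

    pair_box: BoundingBox
    left_roi: BoundingBox
    right_roi: BoundingBox


def crop(frame: np.ndarray, box: BoundingBox) -> np.ndarray:
    """View of ``frame`` restricted to ``box`` (no copy)."""
    return frame[box.y : box.bottom, box.x : box.right]


# ---------------------------------------------------------------------------
# default detector: dark blob pair


@dataclass(frozen=True)
class BlobPairConfig:
    """Tuning of the default dark-blob-pair detector.

    ``pad_fraction`` pads the joint blob box by that fraction of the blob
    separation on every side, leaving context around each iris for the
    boundary search that follows.
    """

    pad_fraction: float = 0.4
    min_blob_area: int = 9
    max_blob_area_fraction: float = 0.05
    min_fill: float = 0.4  # blob area / blob bbox area; disks are ~pi/4
    min_separation_radii: float = 3.0
    max_dy_fraction: float = 0.6  # |vertical| / separation; tilt stays < ~35 deg


def detect_blob_pair(
    frame: np.ndarray, config: BlobPairConfig = BlobPairConfig()
) -> list[tuple[BoundingBox, float]]:
    """Candidate eye-pair boxes from the two darkest compact blobs.

    Pixels darker than the midpoint between the frame minimum and median are
    segmented into connected components; components are filtered for
    plausible size and compactness, and the darkest roughly-horizontal pair
    is returned as a single padded candidate.  Returns an empty list when no
    such pair exists.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    lo = float(frame.min())
    med = float(np.median(frame))
    thr = 0.5 * (lo + med)
    mask = frame < thr
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels, intensity_image=frame)
    max_area = config.max_blob_area_fraction * frame.size
    blobs = []
    for p in props:
        if not config.min_blob_area <= p.area <= max_area:
            continue
        r0, c0, r1, c1 = p.bbox
        if p.area / ((r1 - r0) * (c1 - c0)) < config.min_fill:
            continue
        radius = math.sqrt(p.area / math.pi)
        if radius > min(h, w) / 4:
            continue
        blobs.append((p.intensity_mean, p.centroid, p.bbox, radius))
    if len(blobs) < 2:
        return []
    blobs.sort(key=lambda b: b[0])  # darkest first
    best = None
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            mi, (yi, xi), _, ri = blobs[i]
            mj, (yj, xj), _, rj = blobs[j]
            sep = math.hypot(xi - xj, yi - yj)
            if sep < config.min_separation_radii * max(ri, rj):
                continue
            if abs(yi - yj) > config.max_dy_fraction * sep:
                continue
            darkness = mi + mj
            if best is None or darkness < best[0]:
                best = (darkness, blobs[i], blobs[j], sep)
    if best is None:
        return []
    darkness, bi, bj, sep = best
    r0 = min(bi[2][0], bj[2][0])
    c0 = min(bi[2][1], bj[2][1])
    r1 = max(bi[2][2], bj[2][2])
    c1 = max(bi[2][3], bj[2][3])
    pad = int(round(config.pad_fraction * sep))
    x0 = max(c0 - pad, 0)
    y0 = max(r0 - pad, 0)
    x1 = min(c1 + pad, w)
    y1 = min(r1 + pad, h)
    box = BoundingBox(x=x0, y=y0, width=x1 - x0, height=y1 - y0)
    return [(box, 255.0 - darkness / 2.0)]


EyePairDetector = Callable[[np.ndarray], Sequence[tuple[BoundingBox, float]]]


def detect_eye_pair(
    frame: np.ndarray, detector: EyePairDetector | None = None
) -> BoundingBox:
    """Highest-confidence eye-pair box from the configured detector.

    Raises :class:`DetectionFailure` when the detector returns nothing; the
    caller is free to retry on the next frame.
    """
    if frame.size == 0:
        raise InvalidGeometryError("empty frame")
    detections = (detector or detect_blob_pair)(frame)
    if not detections:
        raise DetectionFailure("no eye-pair candidate found")
    box, _score = max(detections, key=lambda d: d[1])
    return box


def split_eye_region(frame: np.ndarray, pair_box: BoundingBox) -> EyeRegions:
    """Split an eye-pair box into left and right halves.

    For odd widths the left half gets the smaller part.  The returned boxes
    carry their full-frame offsets, so circle fits computed inside a half
    can be mapped back to frame coordinates exactly.
    """
    if pair_box.width < 2:
        raise InvalidGeometryError("pair box too narrow to split")
    h, w = frame.shape
    if pair_box.x < 0 or pair_box.y < 0 or pair_box.right > w or pair_box.bottom > h:
        raise InvalidGeometryError("pair box exceeds the frame")
    left_w = pair_box.width // 2
    left = BoundingBox(pair_box.x, pair_box.y, left_w, pair_box.height)
    right = BoundingBox(
        pair_box.x + left_w, pair_box.y, pair_box.width - left_w, pair_box.height
    )
    return EyeRegions(pair_box=pair_box, left_roi=left, right_roi=right)
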