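"""Synthetic scenes with exact ground truth.

A pinhole camera renders two kinds of scenes used throughout the package:

* **calibration templates** — two dark filled circles on a light background,
  separated by a physical interpupillary distance (IPD) and rotated in the
  frontal plane by a known head-tilt (roll) angle, standing in for a printed
  circle-pair template mounted on a goniometer;
* **stylized eye frames** — per eye a bright sclera ellipse, a dark iris
  disk, a darker concentric pupil disk and an optional specular highlight,
  standing in for webcam frames of a subject.

Every render returns the frame together with a :class:`SceneTruth` carrying
the exact sub-pixel pupil/circle centers, so detector and pipeline accuracy
can be measured against ground truth.

Conventions (shared by every module): image origin at the top-left corner,
x to the right, y downward, 0-based, pixel centers on integer coordinates.
Positive tilt is a rightward head rotation, which raises the right pupil in
the image (smaller y), so the vertical separation dy = y_left - y_right is
positive.  Intensities live on a 0..255 scale in float arrays.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .errors import ConfigError, InvalidGeometryError

__all__ = [
    "CameraModel",
    "SceneTruth",
    "EyeStyle",
    "project_point",
    "make_eye_scene",
    "render_template",
    "render_eye_frame",
    "render_sequence",
    "write_frames",
    "read_frames",
]


@dataclass(frozen=True)
class CameraModel:
    """Distortion-free pinhole camera.

    Defaults model a 720p laptop webcam: 1280x720 frames and a focal length
    of 1000 px, which puts a 65 mm IPD at 500 mm around 130 px.
    """

    image_width: int = 1280
    image_height: int = 720
    focal_length: float = 1000.0
    principal_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.focal_length <= 0:
            raise ConfigError("focal_length must be positive")
        if self.principal_point is None:
            object.__setattr__(
                self,
                "principal_point",
                (self.image_width / 2.0, self.image_height / 2.0),
            )
        px, py = self.principal_point
        if not (0 <= px < self.image_width and 0 <= py < self.image_height):
            raise ConfigError("principal point must lie inside the image")


@dataclass(frozen=True)
class SceneTruth:
    """Exact ground truth for one rendered scene.

    Pixel coordinates are sub-pixel projections of the physical layout;
    ``tilt_deg`` is positive for rightward rotation.
    """

    ipd_mm: float
    distance_mm: float
    tilt_deg: float
    left_pupil_px: tuple[float, float]
    right_pupil_px: tuple[float, float]
    iris_radius_px: float
    pupil_radius_px: float

    def __post_init__(self) -> None:
        if not 45.0 <= self.ipd_mm <= 85.0:
            raise ConfigError("ipd_mm must be within 45..85 mm")
        if not 235.0 <= self.distance_mm <= 800.0:
            raise ConfigError("distance_mm must be within 235..800 mm")
        if not -25.0 <= self.tilt_deg <= 25.0:
            raise ConfigError("tilt_deg must be within -25..25 degrees")
        if not self.pupil_radius_px < self.iris_radius_px:
            raise ConfigError("pupil radius must be smaller than iris radius")

    @property
    def dy_px(self) -> float:
        """Vertical pupil-center separation y_left - y_right in pixels."""
        return self.left_pupil_px[1] - self.right_pupil_px[1]

    @property
    def ipd_px(self) -> float:
        """Euclidean pupil-center separation in pixels."""
        lx, ly = self.left_pupil_px
        rx, ry = self.right_pupil_px
        return math.hypot(rx - lx, ry - ly)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EyeStyle:
    """Appearance of a rendered eye frame; intensities on the 0..255 scale."""

    iris_darkness: float = 70.0
    sclera_brightness: float = 220.0
    highlight_offset_px: tuple[float, float] | None = (3.0, -2.0)
    noise_sd: float = 0.0
    seed: int = 0
    pupil_darkness: float = 20.0
    background: float = 140.0
    highlight_brightness: float = 250.0
    highlight_radius_px: float = 2.0
    sclera_axes: tuple[float, float] = (2.4, 1.5)  # semi-axes / iris radius

    def __post_init__(self) -> None:
        for name in (
            "iris_darkness",
            "sclera_brightness",
            "pupil_darkness",
            "background",
            "highlight_brightness",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ConfigError(f"{name}={v} outside the 0..255 intensity range")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def project_point(
    camera: CameraModel, point_mm: tuple[float, float, float]
) -> tuple[float, float]:
    """Project a 3-D point (mm, camera frame, z forward) to pixel coordinates.

    y grows downward in both the camera frame and the image.
    """
    x, y, z = point_mm
    if z <= 0:
        raise InvalidGeometryError("point depth must be positive")
    px, py = camera.principal_point
    f = camera.focal_length
    return (px + f * x / z, py + f * y / z)


def _pupil_world_offsets(ipd_mm: float, tilt_deg: float) -> tuple[tuple, tuple]:
    """Left/right pupil offsets (mm) from the inter-pupil midpoint, y down.

    Positive tilt rotates the head rightward, raising the right pupil
    (negative y offset, since y grows downward).
    """
    th = math.radians(tilt_deg)
    half = ipd_mm / 2.0
    left = (-half * math.cos(th), half * math.sin(th))
    right = (half * math.cos(th), -half * math.sin(th))
    return left, right


def make_eye_scene(
    camera: CameraModel,
    ipd_mm: float = 63.0,
    distance_mm: float = 500.0,
    tilt_deg: float = 0.0,
    iris_radius_mm: float = 5.9,
    pupil_radius_mm: float = 2.0,
    center_offset_mm: tuple[float, float] = (0.0, 0.0),
) -> SceneTruth:
    """Build the ground truth for a subject at the given pose.

    ``iris_radius_mm`` defaults to the human average (~11.8 mm iris
    diameter).  ``center_offset_mm`` shifts the inter-pupil midpoint off the
    optical axis.
    """
    loff, roff = _pupil_world_offsets(ipd_mm, tilt_deg)
    cx, cy = center_offset_mm
    left = project_point(camera, (cx + loff[0], cy + loff[1], distance_mm))
    right = project_point(camera, (cx + roff[0], cy + roff[1], distance_mm))
    scale = camera.focal_length / distance_mm
    return SceneTruth(
        ipd_mm=ipd_mm,
        distance_mm=distance_mm,
        tilt_deg=tilt_deg,
        left_pupil_px=left,
        right_pupil_px=right,
        iris_radius_px=iris_radius_mm * scale,
        pupil_radius_px=pupil_radius_mm * scale,
    )


# ---------------------------------------------------------------------------
# rasterization

_SUPERSAMPLE = 4  # sub-pixel grid per axis for anti-aliased edges


def _draw_ellipse(
    img: np.ndarray, cx: float, cy: float, a: float, b: float, value: float
) -> None:
    """Alpha-composite a filled ellipse (semi-axes a, b) onto ``img``.

    Edge coverage is estimated on a 4x4 sub-pixel grid so the recorded
    sub-pixel center truth is meaningful.
    """
    h, w = img.shape
    x0 = max(int(math.floor(cx - a)) - 1, 0)
    x1 = min(int(math.ceil(cx + a)) + 2, w)
    y0 = max(int(math.floor(cy - b)) - 1, 0)
    y1 = min(int(math.ceil(cy + b)) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    offs = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5
    cov = np.zeros((y1 - y0, x1 - x0))
    for oy in offs:
        dy2 = ((ys[:, None] + oy - cy) / b) ** 2
        for ox in offs:
            dx2 = ((xs[None, :] + ox - cx) / a) ** 2
            cov += dx2 + dy2 <= 1.0
    cov /= _SUPERSAMPLE * _SUPERSAMPLE
    region = img[y0:y1, x0:x1]
    region *= 1.0 - cov
    region += value * cov


def _draw_disk(img, cx, cy, r, value) -> None:
    _draw_ellipse(img, cx, cy, r, r, value)


def render_template(
    camera: CameraModel,
    ipd_mm: float,
    tilt_deg: float,
    distance_mm: float,
    circle_radius_mm: float = 5.0,
    *,
    background: float = 230.0,
    foreground: float = 25.0,
) -> tuple[np.ndarray, SceneTruth]:
    """Render the circle-pair calibration template.

    The two circle centers are the projections of two points separated by
    ``ipd_mm`` and rotated by ``tilt_deg`` about their midpoint in the
    frontal plane at depth ``distance_mm``.
    """
    truth = make_eye_scene(
        camera,
        ipd_mm=ipd_mm,
        distance_mm=distance_mm,
        tilt_deg=tilt_deg,
        iris_radius_mm=circle_radius_mm,
        pupil_radius_mm=circle_radius_mm / 2.0,
    )
    r_px = truth.iris_radius_px
    for x, y in (truth.left_pupil_px, truth.right_pupil_px):
        if not (
            r_px <= x <= camera.image_width - 1 - r_px
            and r_px <= y <= camera.image_height - 1 - r_px
        ):
            raise InvalidGeometryError("template circle projects outside the frame")
    img = np.full((camera.image_height, camera.image_width), background, dtype=float)
    for x, y in (truth.left_pupil_px, truth.right_pupil_px):
        _draw_disk(img, x, y, r_px, foreground)
    return img, truth


def render_eye_frame(
    camera: CameraModel,
    scene: SceneTruth,
    style: EyeStyle = EyeStyle(),
) -> tuple[np.ndarray, SceneTruth]:
    """Render one stylized subject frame for the given scene truth.

    Per eye: bright sclera ellipse, dark iris disk, darker concentric pupil
    disk and (optionally) a small bright specular highlight offset from the
    pupil center.  Additive Gaussian noise is seeded, so rendering is a pure
    function of (scene, style).
    """
    h, w = camera.image_height, camera.image_width
    for x, y in (scene.left_pupil_px, scene.right_pupil_px):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise InvalidGeometryError("pupil center outside the frame")
    img = np.full((h, w), style.background, dtype=float)
    ax = style.sclera_axes[0] * scene.iris_radius_px
    ay = style.sclera_axes[1] * scene.iris_radius_px
    for x, y in (scene.left_pupil_px, scene.right_pupil_px):
        _draw_ellipse(img, x, y, ax, ay, style.sclera_brightness)
    for x, y in (scene.left_pupil_px, scene.right_pupil_px):
        _draw_disk(img, x, y, scene.iris_radius_px, style.iris_darkness)
        _draw_disk(img, x, y, scene.pupil_radius_px, style.pupil_darkness)
        if style.highlight_offset_px is not None and style.highlight_radius_px > 0:
            hx, hy = style.highlight_offset_px
            _draw_disk(
                img, x + hx, y + hy, style.highlight_radius_px, style.highlight_brightness
            )
    if style.noise_sd > 0:
        rng = np.random.default_rng(style.seed)
        img = img + rng.normal(0.0, style.noise_sd, img.shape)
    np.clip(img, 0.0, 255.0, out=img)
    return img, scene


def render_sequence(
    camera: CameraModel,
    trajectory: list[SceneTruth],
    style: EyeStyle = EyeStyle(),
) -> list[tuple[np.ndarray, SceneTruth]]:
    """Render one frame per trajectory element, in order.

    Each frame draws its noise from a sub-seed derived from
    ``style.seed`` and the frame index, so the whole sequence is a pure
    function of (trajectory, style) while frames get independent noise.
    """
    if not trajectory:
        raise ConfigError("trajectory must be non-empty")
    out = []
    for i, scene in enumerate(trajectory):
        frame_style = dataclasses.replace(style, seed=style.seed * 100003 + i)
        out.append(render_eye_frame(camera, scene, frame_style))
    return out


# ---------------------------------------------------------------------------
# on-disk interchange: PNG frames plus a JSON ground-truth sidecar


def write_frames(
    directory: str | pathlib.Path,
    rendered: list[tuple[np.ndarray, SceneTruth]],
    prefix: str = "frame",
) -> pathlib.Path:
    """Write PNG frames and a ``truth.json`` sidecar; returns the sidecar path."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, truth) in enumerate(rendered):
        name = f"{prefix}_{i:04d}.png"
        iio.imwrite(directory / name, np.clip(np.rint(img), 0, 255).astype(np.uint8))
        rec = {"frame_index": i, "path": name}
        rec.update(truth.to_dict())
        records.append(rec)
    sidecar = directory / "truth.json"
    sidecar.write_text(json.dumps(records, indent=1))
    return sidecar


def read_frames(directory: str | pathlib.Path, pattern: str = "*.png") -> list[np.ndarray]:
    """Load an image-sequence directory as float frames sorted by filename."""
    directory = pathlib.Path(directory)
    frames = []
    for path in sorted(directory.glob(pattern)):
        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # luminance of RGB(A)
            arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
        frames.append(arr)
    return frames
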