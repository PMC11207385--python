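"""Iris and pupil localization with the integrodifferential operator.

The operator scores a candidate circle (x0, y0, r) by the Gaussian-smoothed
radial derivative of the mean image intensity on the circular contour:

    max_{r, x0, y0} | G_sigma(r) * d/dr  (1/(2 pi r)) oint I(x, y) ds |

and the iris boundary is the circle maximizing that score.  The search is
coarse-to-fine: candidate centers are restricted to dark pixels, the best
candidate is refined on a 1-px grid and finally to sub-pixel resolution by
a quadratic fit of the response surface.  The radius search range is tied
to the size of the detected eye-pair box, since the apparent iris size
shrinks with viewing distance.

The magnitude of the smoothed derivative is maximized (not the signed
value), so both dark-iris-on-light-sclera and inverted styles are accepted.
A circular-Hough route for irises is deliberately not provided here; the
Hough transform in :mod:`ocutilt.calibration` serves the large, high-contrast
template circles only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter1d, map_coordinates
from skimage import measure

from .detect import BoundingBox
from .errors import DetectionFailure, InvalidGeometryError

__all__ = [
    "DaugmanParams",
    "CircleFit",
    "contour_mean_intensity",
    "integrodifferential_response",
    "locate_iris",
    "locate_pupil",
    "radius_bounds_from_box",
    "locate_specular_reflex",
]

_MAX_MASKED_FRACTION = 0.5  # contour samples outside the ROI beyond this: invalid


@dataclass(frozen=True)
class DaugmanParams:
    """Search parameters of the integrodifferential operator.

    sigma is the scale (px) of the 1-D Gaussian smoothing the radial
    derivative; rmin/rmax bound the radius search.
    """

    rmin: float
    rmax: float
    sigma: float = 1.0
    radius_step: float = 0.5
    angular_samples: int = 64
    # Contour samples at or above this intensity are treated as specular
    # occlusions and masked from the mean (None disables the masking).
    specular_saturation: float | None = 245.0

    def __post_init__(self) -> None:
        if not 0 < self.rmin < self.rmax:
            raise InvalidGeometryError("require 0 < rmin < rmax")
        if self.sigma <= 0 or self.radius_step <= 0:
            raise InvalidGeometryError("sigma and radius_step must be positive")
        if self.angular_samples < 16:
            raise InvalidGeometryError("need at least 16 angular samples")

    @property
    def radii(self) -> np.ndarray:
        return np.arange(self.rmin, self.rmax + 0.5 * self.radius_step, self.radius_step)


@dataclass(frozen=True)
class CircleFit:
    """Sub-pixel circle with the operator response that selected it."""

    x: float
    y: float
    radius: float
    response: float

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


def _contour_means(
    image: np.ndarray,
    centers_x: np.ndarray,
    centers_y: np.ndarray,
    radii: np.ndarray,
    angular_samples: int,
    saturation: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean contour intensity for every (center, radius) combination.

    Returns ``(means, valid_fraction)`` of shape (n_centers, n_radii).
    Samples falling outside the image — and, when ``saturation`` is set,
    near-saturated samples (specular highlights) — are masked from the mean
    (standard occlusion handling); the caller decides what fraction is
    tolerable.
    """
    h, w = image.shape
    ang = np.linspace(0.0, 2.0 * np.pi, angular_samples, endpoint=False)
    cos, sin = np.cos(ang), np.sin(ang)
    xs = centers_x[:, None, None] + radii[None, :, None] * cos[None, None, :]
    ys = centers_y[:, None, None] + radii[None, :, None] * sin[None, None, :]
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    vals = map_coordinates(
        image, [ys.ravel(), xs.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(xs.shape)
    if saturation is not None and (image >= saturation).any():
        # Mask the whole highlight with a margin: the partially bright rim
        # of a specular spot would otherwise fake a radial edge.
        occluded = binary_dilation(image >= saturation, iterations=2)
        occ = map_coordinates(
            occluded.astype(float), [ys.ravel(), xs.ravel()], order=1,
            mode="constant", cval=0.0,
        ).reshape(xs.shape)
        inside = inside & (occ < 0.01)
    vals = np.where(inside, vals, np.nan)
    n_in = inside.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        means = np.nansum(vals, axis=-1) / np.where(n_in > 0, n_in, 1)
    means[n_in == 0] = np.nan
    return means, n_in / angular_samples


def contour_mean_intensity(
    image: np.ndarray, x0: float, y0: float, r: float, angular_samples: int = 64
) -> float:
    """Mean of the image over equally spaced samples on one circle.

    Sample points are bilinearly interpolated; samples outside the image are
    masked.  More than half masked raises :class:`InvalidGeometryError`.
    """
    means, frac = _contour_means(
        np.asarray(image, dtype=float),
        np.array([float(x0)]),
        np.array([float(y0)]),
        np.array([float(r)]),
        angular_samples,
    )
    if frac[0, 0] <= _MAX_MASKED_FRACTION:
        raise InvalidGeometryError("more than half the contour lies outside the image")
    return float(means[0, 0])


def _response_profiles(
    image: np.ndarray,
    centers_x: np.ndarray,
    centers_y: np.ndarray,
    params: DaugmanParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed |d mean/d r| profiles for many centers at once.

    Returns ``(radii, responses)`` with responses of shape
    (n_centers, n_radii); radii whose contour is mostly outside the image
    get response -inf, and centers with fewer than 3 valid radii are -inf
    throughout.
    """
    radii = params.radii
    means, frac = _contour_means(
        image, centers_x, centers_y, radii, params.angular_samples,
        saturation=params.specular_saturation,
    )
    valid = frac > _MAX_MASKED_FRACTION
    n_valid = valid.sum(axis=1)
    # Fill masked radii by nearest-valid interpolation so the smoothing
    # window never mixes in NaNs, then invalidate them again afterwards.
    filled = means.copy()
    for i in np.nonzero((~valid).any(axis=1) & (n_valid >= 3))[0]:
        good = valid[i]
        filled[i] = np.interp(radii, radii[good], means[i, good])
    dm = np.gradient(filled, radii, axis=1)
    smoothed = gaussian_filter1d(dm, params.sigma / params.radius_step, axis=1, mode="nearest")
    resp = np.abs(smoothed)
    resp[~valid] = -np.inf
    resp[n_valid < 3, :] = -np.inf
    return radii, resp


def integrodifferential_response(
    image: np.ndarray, x0: float, y0: float, params: DaugmanParams
) -> tuple[float, float]:
    """Best radius at a fixed center and the operator response there.

    Computes the contour-mean profile m(r) over the radius range, takes its
    finite-difference derivative, smooths with a 1-D Gaussian of scale
    sigma, and returns the radius maximizing the absolute smoothed
    derivative together with that maximum.
    """
    image = np.asarray(image, dtype=float)
    radii, resp = _response_profiles(
        image, np.array([float(x0)]), np.array([float(y0)]), params
    )
    profile = resp[0]
    if not np.isfinite(profile).any():
        raise InvalidGeometryError("fewer than 3 radii have a valid contour")
    i = int(np.argmax(profile))
    return float(radii[i]), float(profile[i])


def _pick_best(
    centers_x: np.ndarray, centers_y: np.ndarray, radii: np.ndarray, resp: np.ndarray
) -> tuple[int, int]:
    """Index of the winning (center, radius) under the deterministic
    tie-break order: larger response, then smaller radius, smaller y,
    smaller x."""
    flat = resp.reshape(resp.shape[0], -1)
    best_ci, best_ri, best_key = -1, -1, None
    per_center = np.argmax(flat, axis=1)
    for ci, ri in enumerate(per_center):
        r = resp[ci, ri]
        if not np.isfinite(r):
            continue
        key = (-r, radii[ri], centers_y[ci], centers_x[ci])
        if best_key is None or key < best_key:
            best_key = key
            best_ci, best_ri = ci, ri
    return best_ci, best_ri


def _quadratic_peak_offset(z: np.ndarray) -> tuple[float, float]:
    """Sub-pixel peak of a 3x3 response patch via a least-squares paraboloid.

    Returns the (dx, dy) offset of the stationary point, clamped to the
    [-1, 1] cell; falls back to (0, 0) when the surface is not peaked.
    """
    ys, xs = np.mgrid[-1:2, -1:2]
    A = np.stack(
        [np.ones(9), xs.ravel(), ys.ravel(), xs.ravel() ** 2, ys.ravel() ** 2,
         (xs * ys).ravel()],
        axis=1,
    )
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    _, b, c, d, e, f = coef
    H = np.array([[2 * d, f], [f, 2 * e]])
    det = np.linalg.det(H)
    if det <= 0:  # not a maximum
        return 0.0, 0.0
    dx, dy = np.linalg.solve(H, [-b, -c])
    if not (np.isfinite(dx) and np.isfinite(dy)):
        return 0.0, 0.0
    return float(np.clip(dx, -1, 1)), float(np.clip(dy, -1, 1))


def locate_iris(
    roi: np.ndarray,
    params: DaugmanParams,
    min_response: float = 5.0,
    coarse_step: int = 2,
) -> CircleFit:
    """Iris circle maximizing the integrodifferential response in a ROI.

    Coarse candidate centers are dark pixels on a ``coarse_step`` grid (the
    iris interior is dark by construction); the best candidate is refined on
    a 1-px grid and then to sub-pixel by a quadratic fit of the 3x3
    response surface at the winning radius.  A best response below
    ``min_response`` raises :class:`DetectionFailure`.
    """
    roi = np.asarray(roi, dtype=float)
    h, w = roi.shape
    thr = 0.5 * (float(roi.min()) + float(np.median(roi)))
    dark_y, dark_x = np.nonzero(roi < thr)
    if dark_y.size:
        # anchor the decimation grid to the dark region itself so that
        # integer ROI shifts shift the candidate set identically
        keep = ((dark_y - dark_y.min()) % coarse_step == 0) & (
            (dark_x - dark_x.min()) % coarse_step == 0
        )
    else:
        keep = np.zeros(0, dtype=bool)
    cx, cy = dark_x[keep].astype(float), dark_y[keep].astype(float)
    if cx.size == 0:  # featureless ROI: let the operator judge a sparse grid
        gy, gx = np.mgrid[0:h:3, 0:w:3]
        cx, cy = gx.ravel().astype(float), gy.ravel().astype(float)
    radii, resp = _response_profiles(roi, cx, cy, params)
    best_per_center = resp.max(axis=1)
    if not np.isfinite(best_per_center).any():
        raise DetectionFailure("no candidate center with a valid radius sweep")

    # Refine the best few spatially distinct coarse candidates: the response
    # at an off-grid true center can be undersold at its nearest grid point,
    # so committing to a single coarse winner is unsafe.
    order = np.argsort(-best_per_center)
    seeds: list[tuple[float, float]] = []
    for idx in order:
        if not np.isfinite(best_per_center[idx]) or len(seeds) >= 5:
            break
        if all((cx[idx] - sx) ** 2 + (cy[idx] - sy) ** 2 >= 9 for sx, sy in seeds):
            seeds.append((cx[idx], cy[idx]))
    span = max(coarse_step, 1)
    gy, gx = np.mgrid[-span : span + 1, -span : span + 1]
    rx = np.concatenate([np.clip(sx + gx.ravel(), 0, w - 1) for sx, sy in seeds])
    ry = np.concatenate([np.clip(sy + gy.ravel(), 0, h - 1) for sx, sy in seeds])
    fine = np.unique(np.stack([rx, ry], axis=1), axis=0)
    fx, fy = fine[:, 0].astype(float), fine[:, 1].astype(float)
    radii, resp = _response_profiles(roi, fx, fy, params)
    ci, ri = _pick_best(fx, fy, radii, resp)
    if ci < 0:
        raise DetectionFailure("refinement produced no valid candidate")
    bx, by = float(fx[ci]), float(fy[ci])
    best_r = float(radii[ri])
    best_resp = float(resp[ci, ri])
    if best_resp < min_response:
        raise DetectionFailure(
            f"best operator response {best_resp:.2f} below floor {min_response}"
        )

    # sub-pixel: response surface at the winning radius over a 3x3 center grid
    gy, gx = np.mgrid[-1:2, -1:2]
    sx = (bx + gx.ravel()).astype(float)
    sy = (by + gy.ravel()).astype(float)
    _, sresp = _response_profiles(roi, sx, sy, params)
    surface = sresp[:, ri].reshape(3, 3)
    if np.isfinite(surface).all():
        dx, dy = _quadratic_peak_offset(surface)
    else:
        dx = dy = 0.0
    return CircleFit(x=bx + dx, y=by + dy, radius=best_r, response=best_resp)


def locate_pupil(
    roi: np.ndarray, iris: CircleFit, params: DaugmanParams | None = None
) -> CircleFit:
    """Optional second, inner operator pass for the pupil boundary.

    Searches small radii near the iris center.  The measurement pipeline
    treats iris and pupil as concentric and does not use this refinement.
    """
    if params is None:
        params = DaugmanParams(rmin=2.0, rmax=max(3.0, 0.75 * iris.radius))
    gy, gx = np.mgrid[-2:3, -2:3]
    cx = (iris.x + gx.ravel()).astype(float)
    cy = (iris.y + gy.ravel()).astype(float)
    radii, resp = _response_profiles(np.asarray(roi, dtype=float), cx, cy, params)
    ci, ri = _pick_best(cx, cy, radii, resp)
    if ci < 0:
        raise DetectionFailure("no valid pupil candidate")
    return CircleFit(
        x=float(cx[ci]), y=float(cy[ci]), radius=float(radii[ri]),
        response=float(resp[ci, ri]),
    )


def radius_bounds_from_box(
    pair_box: BoundingBox, fractions: tuple[float, float] = (0.15, 0.45)
) -> tuple[float, float]:
    """Radius search range proportional to the eye-pair box height.

    Fixed radii fail across viewing distances because the apparent iris
    size changes; tying the bounds to the detected box keeps the search
    scale-adaptive.  Both bounds are clamped to at least 3 px; a box too
    small to leave room between them raises :class:`DetectionFailure`.
    """
    fmin, fmax = fractions
    if not 0 < fmin < fmax < 1:
        raise InvalidGeometryError("require 0 < fmin < fmax < 1")
    rmin = max(3.0, fmin * pair_box.height)
    rmax = max(3.0, fmax * pair_box.height)
    if rmax <= rmin:
        raise DetectionFailure("pair box too small for a meaningful radius range")
    return rmin, rmax


def locate_specular_reflex(
    roi: np.ndarray,
    iris: CircleFit,
    percentile: float = 95.0,
    min_contrast: float = 30.0,
    rim_margin_px: float = 1.5,
) -> tuple[float, float] | None:
    """Centroid of the corneal specular highlight inside the iris circle.

    The highlight is the brightest connected region strictly inside the
    iris whose intensity reaches the given percentile of the iris disk and
    exceeds the disk median by ``min_contrast`` (guarding against
    highlight-free irises).  ``rim_margin_px`` keeps the blurred iris/sclera
    rim out of the disk so it cannot pose as a highlight.  Returns ``None``
    when no such region exists — a non-fatal absence; the circle-fit center
    is used instead.
    """
    roi = np.asarray(roi, dtype=float)
    h, w = roi.shape
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (xx - iris.x) ** 2 + (yy - iris.y) ** 2 < max(
        iris.radius - rim_margin_px, 1.0
    ) ** 2
    vals = roi[inside]
    if vals.size == 0:
        return None
    med = float(np.median(vals))
    if float(vals.max()) < med + min_contrast:
        return None
    thr = max(float(np.percentile(vals, percentile)), med + min_contrast)
    bright = inside & (roi >= thr)
    if not bright.any():
        return None
    labels = measure.label(bright, connectivity=2)
    props = measure.regionprops(labels, intensity_image=roi)
    best = max(props, key=lambda p: p.intensity_mean)
    cy, cx = best.centroid_weighted
    return (float(cx), float(cy))
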