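"""Integrodifferential iris localization, including a brute-force oracle."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from ocutilt import (
    BoundingBox,
    CameraModel,
    DaugmanParams,
    DetectionFailure,
    EyeStyle,
    InvalidGeometryError,
    contour_mean_intensity,
    integrodifferential_response,
    locate_iris,
    locate_specular_reflex,
    make_eye_scene,
    radius_bounds_from_box,
    render_eye_frame,
)
from ocutilt.daugman import CircleFit


def _disk_image(size=60, cx=None, cy=None, r=20.0, inside=10.0, outside=200.0):
    cx = size / 2 if cx is None else cx
    cy = size / 2 if cy is None else cy
    yy, xx = np.mgrid[0:size, 0:size]
    return np.where(np.hypot(xx - cx, yy - cy) <= r, inside, outside).astype(float)


def _eye_roi(noise_sd=0.0, seed=0, highlight=(3.0, -2.0)):
    """A 96x96 single-eye ROI cropped from a rendered two-eye frame.

    Returns (roi, true_center_in_roi_coords, true_iris_radius_px).
    """
    cam = CameraModel(image_width=256, image_height=96, focal_length=600.0)
    scene = make_eye_scene(cam, ipd_mm=65.0, distance_mm=400.0)
    style = EyeStyle(noise_sd=noise_sd, seed=seed, highlight_offset_px=highlight)
    frame, _ = render_eye_frame(cam, scene, style)
    x0 = 31
    roi = frame[:, x0 : x0 + 96].copy()
    lx, ly = scene.left_pupil_px
    return roi, (lx - x0, ly), scene.iris_radius_px


class TestContourMean:
    def test_constant_image_gives_the_constant(self):
        img = np.full((50, 50), 37.0)
        assert contour_mean_intensity(img, 25, 25, 10) == pytest.approx(37.0)

    def test_circle_inside_and_outside_dark_disk(self):
        img = _disk_image()
        assert contour_mean_intensity(img, 30, 30, 10) == pytest.approx(10.0)
        assert contour_mean_intensity(img, 30, 30, 28) == pytest.approx(200.0)

    def test_edge_straddling_circle_is_between(self):
        img = _disk_image()
        v = contour_mean_intensity(img, 30, 30, 20)
        assert 10.0 < v < 200.0

    def test_mostly_outside_circle_invalid(self):
        img = _disk_image()
        with pytest.raises(InvalidGeometryError):
            contour_mean_intensity(img, 2, 2, 25)


class TestResponse:
    def test_recovers_disk_radius(self):
        img = _disk_image(r=20.0)
        params = DaugmanParams(rmin=10, rmax=30, radius_step=1.0)
        r, resp = integrodifferential_response(img, 30, 30, params)
        assert abs(r - 20.0) <= 1.0
        assert resp > 10.0

    def test_constant_image_has_no_response(self):
        img = np.full((60, 60), 120.0)
        params = DaugmanParams(rmin=5, rmax=20)
        _, resp = integrodifferential_response(img, 30, 30, params)
        assert resp < 1e-9

    def test_invariant_to_intensity_offset(self):
        img = _disk_image()
        params = DaugmanParams(rmin=10, rmax=28)
        r1, v1 = integrodifferential_response(img, 30, 30, params)
        r2, v2 = integrodifferential_response(img + 40.0, 30, 30, params)
        assert r1 == r2
        assert v1 == pytest.approx(v2, abs=1e-9)


class TestLocateIris:
    def test_recovers_rendered_eye_within_one_pixel(self):
        roi, (tx, ty), tr = _eye_roi()
        params = DaugmanParams(rmin=0.5 * tr, rmax=1.6 * tr)
        fit = locate_iris(roi, params)
        assert math.hypot(fit.x - tx, fit.y - ty) < 1.0
        assert abs(fit.radius - tr) < 1.0

    def test_rotating_roi_180_degrees_rotates_the_fit(self):
        roi, _, tr = _eye_roi()
        params = DaugmanParams(rmin=0.5 * tr, rmax=1.6 * tr)
        fit = locate_iris(roi, params)
        rot = np.rot90(roi, 2).copy()
        fit_rot = locate_iris(rot, params)
        h, w = roi.shape
        assert fit_rot.x == pytest.approx(w - 1 - fit.x, abs=0.5)
        assert fit_rot.y == pytest.approx(h - 1 - fit.y, abs=0.5)
        assert fit_rot.radius == pytest.approx(fit.radius, abs=0.51)

    def test_translation_equivariance_for_integer_shifts(self):
        roi, _, tr = _eye_roi()
        params = DaugmanParams(rmin=0.5 * tr, rmax=1.6 * tr)
        fit = locate_iris(roi, params)
        shifted = np.roll(roi, (3, 5), axis=(0, 1))
        fit2 = locate_iris(shifted, params)
        assert fit2.x - fit.x == pytest.approx(5.0, abs=1e-6)
        assert fit2.y - fit.y == pytest.approx(3.0, abs=1e-6)
        assert fit2.radius == fit.radius

    def test_featureless_roi_fails(self):
        params = DaugmanParams(rmin=5, rmax=15)
        with pytest.raises(DetectionFailure):
            locate_iris(np.full((60, 60), 100.0), params)

    def test_noise_robustness_at_sd5(self):
        """Center stays within 2 px of truth in >= 95% of noisy renders."""
        hits = 0
        n = 50
        for seed in range(n):
            roi, (tx, ty), tr = _eye_roi(noise_sd=5.0, seed=seed)
            params = DaugmanParams(rmin=0.5 * tr, rmax=1.6 * tr)
            try:
                fit = locate_iris(roi, params)
            except DetectionFailure:
                continue
            if math.hypot(fit.x - tx, fit.y - ty) < 2.0:
                hits += 1
        assert hits / n >= 0.95

    def test_center_error_degrades_monotonically_with_noise(self):
        """Mean center error is non-decreasing in the noise level."""
        levels = (0.0, 2.0, 5.0, 10.0)
        means = []
        for sd in levels:
            errs = []
            for seed in range(30):
                roi, (tx, ty), tr = _eye_roi(noise_sd=sd, seed=1000 + seed)
                params = DaugmanParams(rmin=0.5 * tr, rmax=1.6 * tr)
                try:
                    fit = locate_iris(roi, params)
                    errs.append(math.hypot(fit.x - tx, fit.y - ty))
                except DetectionFailure:
                    errs.append(2 * tr)
            means.append(np.mean(errs))
        for lo, hi in zip(means, means[1:]):
            assert lo <= hi + 0.05  # small slack for the Monte-Carlo mean


class TestBruteForceOracle:
    def test_matches_exhaustive_maximization_on_small_roi(self):
        """On a small ROI the coarse-to-fine search equals brute force over
        all integer (x0, y0, r) within 1 px in center and radius."""
        roi, _, tr = _eye_roi(highlight=None)
        roi = roi[16:80, 16:80]  # <= 64 x 64
        params = DaugmanParams(
            rmin=0.6 * tr, rmax=1.5 * tr, radius_step=0.5, sigma=1.0,
            specular_saturation=None,
        )
        fit = locate_iris(roi, params)
        bx, by, br = _brute_force_daugman(roi, params)
        assert abs(fit.x - bx) <= 1.0
        assert abs(fit.y - by) <= 1.0
        assert abs(fit.radius - br) <= 1.0


def _brute_force_daugman(image, params):
    """Independent exhaustive maximization of the operator.

    Plain loops and explicit bilinear interpolation; shares no code with the
    implementation under test.
    """
    h, w = image.shape
    radii = np.arange(params.rmin, params.rmax + params.radius_step / 2, params.radius_step)
    ang = np.linspace(0, 2 * np.pi, params.angular_samples, endpoint=False)
    best = (-np.inf, None)
    for y0 in range(h):
        for x0 in range(w):
            ms = np.full(len(radii), np.nan)
            for k, r in enumerate(radii):
                xs = x0 + r * np.cos(ang)
                ys = y0 + r * np.sin(ang)
                ok = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
                if ok.mean() <= 0.5:
                    continue
                xs, ys = xs[ok], ys[ok]
                xi, yi = np.floor(xs).astype(int), np.floor(ys).astype(int)
                xi = np.minimum(xi, w - 2)
                yi = np.minimum(yi, h - 2)
                fx, fy = xs - xi, ys - yi
                vals = (
                    image[yi, xi] * (1 - fx) * (1 - fy)
                    + image[yi, xi + 1] * fx * (1 - fy)
                    + image[yi + 1, xi] * (1 - fx) * fy
                    + image[yi + 1, xi + 1] * fx * fy
                )
                ms[k] = vals.mean()
            good = np.isfinite(ms)
            if good.sum() < 3:
                continue
            filled = np.interp(radii, radii[good], ms[good])
            dm = np.gradient(filled, radii)
            sm = gaussian_filter1d(dm, params.sigma / params.radius_step, mode="nearest")
            sm = np.abs(sm)
            sm[~good] = -np.inf
            k = int(np.argmax(sm))
            if sm[k] > best[0]:
                best = (sm[k], (x0, y0, radii[k]))
    return best[1]


class TestRadiusBounds:
    def test_fractions_of_box_height(self):
        box = BoundingBox(0, 0, 200, 60)
        assert radius_bounds_from_box(box, (0.15, 0.45)) == (9.0, 27.0)

    def test_linearity_above_floor(self):
        full = radius_bounds_from_box(BoundingBox(0, 0, 200, 80), (0.15, 0.45))
        half = radius_bounds_from_box(BoundingBox(0, 0, 200, 40), (0.15, 0.45))
        assert half == (full[0] / 2, full[1] / 2)

    def test_small_box_clamps_rmin_to_three(self):
        rmin, rmax = radius_bounds_from_box(BoundingBox(0, 0, 50, 10), (0.15, 0.45))
        assert rmin == 3.0
        assert rmax == pytest.approx(4.5)

    def test_box_too_small_fails(self):
        with pytest.raises(DetectionFailure):
            radius_bounds_from_box(BoundingBox(0, 0, 50, 5), (0.15, 0.45))

    def test_bad_fractions_rejected(self):
        with pytest.raises(InvalidGeometryError):
            radius_bounds_from_box(BoundingBox(0, 0, 50, 60), (0.5, 0.4))


class TestSpecularReflex:
    def test_recovers_highlight_within_one_pixel(self):
        roi, (tx, ty), tr = _eye_roi(highlight=(3.0, -2.0))
        iris = CircleFit(x=tx, y=ty, radius=tr, response=1.0)
        reflex = locate_specular_reflex(roi, iris)
        assert reflex is not None
        assert math.hypot(reflex[0] - (tx + 3), reflex[1] - (ty - 2)) < 1.0

    def test_absent_highlight_returns_none(self):
        roi, (tx, ty), tr = _eye_roi(highlight=None)
        iris = CircleFit(x=tx, y=ty, radius=tr, response=1.0)
        assert locate_specular_reflex(roi, iris) is None

    def test_reflex_lies_inside_the_iris_circle(self):
        roi, (tx, ty), tr = _eye_roi(highlight=(4.0, 3.0))
        iris = CircleFit(x=tx, y=ty, radius=tr, response=1.0)
        reflex = locate_specular_reflex(roi, iris)
        assert math.hypot(reflex[0] - tx, reflex[1] - ty) < tr
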