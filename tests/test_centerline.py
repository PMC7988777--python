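"""Centerline fitting and curved-path profiling against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

import notoquant as nq
from notoquant.centerline import arc_length_samples

from conftest import random_tube_geometry


def brute_force_bilinear(image: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Textbook bilinear interpolation, written independently of the package."""
    im = image.astype(np.float64)
    x0 = np.clip(np.floor(x).astype(int), 0, im.shape[1] - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, im.shape[0] - 2)
    fx, fy = x - x0, y - y0
    return (
        im[y0, x0] * (1 - fx) * (1 - fy)
        + im[y0, x0 + 1] * fx * (1 - fy)
        + im[y0 + 1, x0] * (1 - fx) * fy
        + im[y0 + 1, x0 + 1] * fx * fy
    )


class TestFit:
    def test_horizontal_line_recovers_constant(self):
        pix = np.zeros((20, 100), dtype=bool)
        pix[5, :] = True
        curve = nq.fit_polynomial_centerline(nq.NotochordMask(pix), degree=6)
        assert curve.coefficients[0] == pytest.approx(5.0, abs=1e-8)
        assert all(abs(c) <= 1e-8 for c in curve.coefficients[1:])
        assert curve.x_domain == (0.0, 99.0)

    def test_rasterised_quadratic_recovered_within_half_pixel(self):
        xs = np.arange(100)
        ys = np.round(0.001 * xs**2 + 0.2 * xs + 10).astype(int)
        pix = np.zeros((50, 100), dtype=bool)
        pix[ys, xs] = True
        curve = nq.fit_polynomial_centerline(nq.NotochordMask(pix), degree=6)
        true_y = 0.001 * xs**2 + 0.2 * xs + 10
        assert np.max(np.abs(curve.y(xs) - true_y)) < 0.5

    def test_under_determined_fit_rejected(self):
        pix = np.zeros((10, 10), dtype=bool)
        pix[2, [1, 3, 5, 7, 9]] = True  # 5 distinct x < degree+1
        with pytest.raises(nq.CenterlineFitError, match="distinct x"):
            nq.fit_polynomial_centerline(nq.NotochordMask(pix), degree=6)


    def test_curve_json_roundtrip(self):
        curve = nq.PolynomialCenterline(2, (10.0, 0.2, 0.001), (0.0, 99.0))
        back = nq.PolynomialCenterline.from_json(curve.to_json())
        assert back == curve


class TestArcLengthSampling:
    def test_horizontal_line_unit_steps(self):
        curve = nq.PolynomialCenterline(0, (7.0,), (3.0, 13.0))
        pos, pts, tan = arc_length_samples(curve, step=1.0)
        np.testing.assert_allclose(pts[:, 0], np.arange(3.0, 14.0), atol=1e-9)
        np.testing.assert_allclose(pts[:, 1], 7.0)
        np.testing.assert_allclose(tan, [[1.0, 0.0]] * len(pos), atol=1e-12)

    def test_diagonal_root2_steps_advance_x_by_one(self):
        curve = nq.PolynomialCenterline(1, (0.0, 1.0), (0.0, 10.0))
        pos, pts, _ = arc_length_samples(curve, step=np.sqrt(2))
        np.testing.assert_allclose(np.diff(pts[:, 0]), 1.0, atol=1e-6)

    def test_total_arc_length_matches_quadrature(self):
        curve = nq.PolynomialCenterline(2, (10.0, 0.2, 0.001), (0.0, 99.0))
        pos, _, _ = arc_length_samples(curve, step=1.0)
        oracle, _ = quad(lambda x: np.hypot(1.0, 0.2 + 0.002 * x), 0.0, 99.0)
        assert abs(pos[-1] - oracle) < 1e-3

    def test_spacing_is_uniform_except_final_sample(self):
        curve = nq.PolynomialCenterline(2, (20.0, 0.1, 0.002), (0.0, 150.0))
        pos, _, _ = arc_length_samples(curve, step=1.0)
        gaps = np.diff(pos)
        np.testing.assert_allclose(gaps[:-1], 1.0, atol=1e-6)
        assert 0 < gaps[-1] <= 1.0 + 1e-6


class TestExtractProfile:
    def test_constant_tube_profile_is_constant(self, straight_image):
        curve = nq.PolynomialCenterline(0, (50.0,), (0.0, 199.0))
        prof = nq.extract_profile(straight_image, curve)
        np.testing.assert_allclose(prof.intensities, 100.0)

    def test_ramp_field_reproduced_exactly(self):
        img = np.tile(np.arange(120, dtype=np.float64), (40, 1))
        curve = nq.PolynomialCenterline(0, (20.0,), (0.0, 119.0))
        prof = nq.extract_profile(img, curve)
        np.testing.assert_allclose(prof.intensities, prof.arc_positions, atol=1e-9)

    def test_affine_field_interpolated_exactly_on_curved_path(self):
        h, w = 80, 200
        yy, xx = np.mgrid[0:h, 0:w]
        img = 2.0 * xx + 3.0 * yy + 7.0
        curve = nq.PolynomialCenterline(2, (40.0, 0.05, -0.0004), (5.0, 190.0))
        prof = nq.extract_profile(img, curve, step=0.7)
        pos, pts, _ = arc_length_samples(curve, step=0.7)
        expected = 2.0 * pts[:, 0] + 3.0 * pts[:, 1] + 7.0
        np.testing.assert_allclose(prof.intensities, expected, atol=1e-9)

    def test_curved_profile_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        tube = random_tube_geometry(rng)
        truth = nq.GroundTruth(
            tube=tube, lesions=(nq.LesionSpec(300, 60, 6),), noise_sigma=0.0
        )
        img = nq.generate_notochord_image(truth)
        curve = nq.PolynomialCenterline(
            len(tube.centerline_coeffs) - 1,
            tube.centerline_coeffs,
            (0.0, float(tube.image_width - 1)),
        )
        prof = nq.extract_profile(img, curve)
        _, pts, _ = arc_length_samples(curve, step=1.0)
        oracle = brute_force_bilinear(img, pts[:, 0], pts[:, 1])
        assert np.max(np.abs(prof.intensities - oracle)) < 1e-9

    def test_out_of_bounds_samples_dropped_and_counted(self):
        img = np.full((30, 50), 10.0)
        # line exits the top of the image over part of the domain
        curve = nq.PolynomialCenterline(1, (5.0, -0.4), (0.0, 49.0))
        prof = nq.extract_profile(img, curve)
        assert prof.n_dropped > 0
        assert len(prof) + prof.n_dropped == len(arc_length_samples(curve, 1.0)[0])

    def test_all_samples_out_of_bounds_is_an_error(self):
        img = np.full((10, 10), 5.0)
        curve = nq.PolynomialCenterline(0, (500.0,), (0.0, 9.0))
        with pytest.raises(nq.ProfileError):
            nq.extract_profile(img, curve)

    def test_linewidth_averages_normal_samples(self, straight_image):
        img = straight_image.astype(float).copy()
        img[49, :] = 130.0  # one bright row inside the tube
        curve = nq.PolynomialCenterline(0, (50.0,), (0.0, 199.0))
        wide = nq.extract_profile(img, curve, linewidth=3)
        np.testing.assert_allclose(wide.intensities, (130.0 + 100.0 + 100.0) / 3)

    def test_even_linewidth_rejected(self, straight_image):
        curve = nq.PolynomialCenterline(0, (50.0,), (0.0, 199.0))
        with pytest.raises(nq.ProfileError):
            nq.extract_profile(straight_image, curve, linewidth=2)

    def test_halving_step_barely_changes_smooth_mean(self):
        rng = np.random.default_rng(23)
        tube = random_tube_geometry(rng)
        tube = nq.TubeModel(
            tube.image_height, tube.image_width, tube.centerline_coeffs,
            tube.tube_radius, tube.tube_intensity, tube.background_intensity,
            edge_softness=2.0,
        )
        img = nq.generate_notochord_image(nq.GroundTruth(tube=tube)).astype(float)
        curve = nq.PolynomialCenterline(
            len(tube.centerline_coeffs) - 1, tube.centerline_coeffs,
            (0.0, float(tube.image_width - 1)),
        )
        m1 = nq.severity_score(nq.extract_profile(img, curve, step=1.0)).mean_intensity
        m2 = nq.severity_score(nq.extract_profile(img, curve, step=0.5)).mean_intensity
        assert abs(m1 - m2) < 1e-3

    def test_translation_equivariance_in_y(self):
        tube = nq.TubeModel(150, 300, (60.0, 0.05), 6.0, 100.0, 10.0)
        img1 = nq.generate_notochord_image(nq.GroundTruth(tube=tube))
        img2 = np.roll(img1, 7, axis=0)
        m1 = nq.largest_component(nq.threshold_mask(img1, 50))
        m2 = nq.largest_component(nq.threshold_mask(img2, 50))
        c1 = nq.fit_polynomial_centerline(m1)
        c2 = nq.fit_polynomial_centerline(m2)
        xs = np.linspace(0, 299, 100)
        np.testing.assert_allclose(c2.y(xs), c1.y(xs) + 7.0, atol=1e-9)
        p1 = nq.extract_profile(img1, c1)
        p2 = nq.extract_profile(img2, c2)
        np.testing.assert_allclose(p1.intensities, p2.intensities, atol=1e-9)
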