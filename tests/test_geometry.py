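import numpy as np
import pytest

from parpolar import attachment_profile, ellipse_curvature, triangle_curvature


class TestEllipse:
    def test_circle_limit_constant_curvature(self):
        prof = ellipse_curvature(10.0, 10.0, 128)
        assert np.allclose(prof.curvature, 0.1, rtol=1e-6)
        assert prof.baseline == pytest.approx(0.1)

    def test_polar_and_lateral_extrema(self):
        a, b = 25.0, 15.0
        prof = ellipse_curvature(a, b, 512)
        assert prof.curvature.max() == pytest.approx(a / b**2, rel=1e-3)
        assert prof.curvature.min() == pytest.approx(b / a**2, rel=1e-3)
        # poles sit at position 0 and half the perimeter
        assert prof.curvature[0] == pytest.approx(a / b**2, rel=1e-3)
        mid = prof.positions.size // 2
        assert prof.curvature[mid] == pytest.approx(a / b**2, rel=1e-2)

    @pytest.mark.parametrize("ab", [(25.0, 15.0), (30.0, 10.0), (12.0, 11.0)])
    def test_total_turning_is_2pi(self, ab):
        prof = ellipse_curvature(*ab, 1024)
        assert prof.total_turning == pytest.approx(2.0 * np.pi, abs=1e-4)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            ellipse_curvature(10.0, 15.0, 128)  # a < b
        with pytest.raises(ValueError):
            ellipse_curvature(25.0, 15.0, 8)  # too few points


class TestTriangle:
    def test_corner_arcs_and_turning(self):
        side, r = 40.0, 5.0
        prof = triangle_curvature(side, r, 1024)
        dx = prof.spacing
        arc_len = np.sum(prof.curvature > 0) * dx
        assert arc_len == pytest.approx(3 * r * 2 * np.pi / 3, rel=0.02)
        assert prof.total_turning == pytest.approx(2.0 * np.pi, rel=1e-2)
        assert prof.baseline == 0.0

    def test_perimeter_closed_form(self):
        side, r = 40.0, 5.0
        prof = triangle_curvature(side, r, 256)
        expected = 3 * (side - 2 * np.sqrt(3) * r) + 2 * np.pi * r
        assert prof.circumference == pytest.approx(expected, rel=1e-6)

    def test_inscribed_circle_limit(self):
        side = 40.0
        r = side / (2 * np.sqrt(3)) * 0.999
        prof = triangle_curvature(side, r, 512)
        # contour tends to the inscribed circle: excess curvature -> 0
        excess = prof.curvature - prof.baseline
        assert np.max(excess) * r < 0.01

    def test_unequal_radii(self):
        prof = triangle_curvature(40.0, (4.0, 5.0, 6.0), 512)
        peaks = sorted(set(prof.curvature[prof.curvature > 0]))
        assert peaks == pytest.approx([1 / 6.0, 1 / 5.0, 1 / 4.0], rel=1e-9)

    def test_impossible_rounding_rejected(self):
        with pytest.raises(ValueError):
            triangle_curvature(40.0, 12.0, 256)  # r >= side/(2*sqrt(3))


class TestAttachmentProfile:
    def test_zero_gain_uniform(self):
        prof = ellipse_curvature(25.0, 15.0, 256)
        kon = attachment_profile(prof, 0.05, 0.0)
        assert np.allclose(kon, 0.05)

    def test_circle_uniform(self):
        prof = ellipse_curvature(10.0, 10.0, 256)
        kon = attachment_profile(prof, 0.05, 2.0)
        assert np.allclose(kon, 0.05, atol=1e-9)

    def test_ellipse_peak_enhancement(self):
        prof = ellipse_curvature(25.0, 15.0, 512)
        alpha = 2.0
        kon = attachment_profile(prof, 0.05, alpha)
        want = 0.05 + alpha * (25 / 15**2 - 15 / 25**2)
        assert kon.max() == pytest.approx(want, rel=1e-3)
        assert np.all(kon >= 0.05 - 1e-12)

    def test_local_maxima_counts(self):
        kon_e = attachment_profile(ellipse_curvature(25.0, 15.0, 512), 0.05, 1.0, smooth_sigma=3.0)
        kon_t = attachment_profile(triangle_curvature(40.0, 5.0, 512), 0.05, 1.0, smooth_sigma=3.0)

        def n_local_maxima(y):
            return int(np.sum((y > np.roll(y, 1)) & (y >= np.roll(y, -1)) & (y > y.min() + 1e-9)))

        assert n_local_maxima(kon_e) == 2
        assert n_local_maxima(kon_t) == 3

    def test_boost_cap_saturates(self):
        prof = triangle_curvature(40.0, 5.0, 256)
        kon = attachment_profile(prof, 0.05, 1e6, boost_cap=8.0)
        assert kon.max() <= 0.05 * 9.0 + 1e-9

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            attachment_profile(ellipse_curvature(25.0, 15.0, 64), 0.05, -1.0)
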