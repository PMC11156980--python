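"""Tests of the concentric circle/ellipse model geometry and fitting."""

import numpy as np
import pytest

from retinaos import (
    AxisLine,
    EllipseSpec,
    VN_AXIS,
    VT_AXIS,
    area_between_fits,
    fit_anchor_and_aspect,
    fit_quadratic,
    line_conic_intersection,
    predicted_angle_curve,
    tangent_axis_at_point,
    tangent_axis_through_point,
)
from retinaos.angles import axis_difference, wrap_orientation
from retinaos.retinamap import deviation_vs_distance


class TestLineConicIntersection:
    def test_unit_circle_horizontal_line(self):
        pts, ts = line_conic_intersection(
            AxisLine(angle_deg=0.0), EllipseSpec(0, 0, 1, 1)
        )
        assert sorted(np.round(pts[:, 0], 12)) == [-1.0, 1.0]
        assert np.allclose(pts[:, 1], 0.0)

    def test_no_intersection(self):
        pts, ts = line_conic_intersection(
            AxisLine(angle_deg=0.0, origin=(0.0, 2.0)), EllipseSpec(0, 0, 1, 1)
        )
        assert len(pts) == 0

    def test_tangency_single_point(self):
        pts, _ = line_conic_intersection(
            AxisLine(angle_deg=0.0, origin=(0.0, 1.0)), EllipseSpec(0, 0, 1, 1)
        )
        assert len(pts) == 1
        assert pts[0] == pytest.approx([0.0, 1.0])

    def test_ellipse_diagonal_line(self):
        # x^2/4 + y^2 = 1 with y = x: x = +/- sqrt(4/5)
        pts, _ = line_conic_intersection(
            AxisLine(angle_deg=45.0), EllipseSpec(0, 0, 2, 1)
        )
        x = np.sort(pts[:, 0])
        assert x == pytest.approx([-np.sqrt(4 / 5), np.sqrt(4 / 5)])
        assert np.allclose(pts[:, 0], pts[:, 1])


class TestTangentAxis:
    def test_circle_ventral_pole_horizontal(self):
        # tangent at the bottom of a circle is horizontal
        c = EllipseSpec(0, 0, 500, 500)
        assert tangent_axis_at_point(c, (0.0, -500.0)) == pytest.approx(0.0)

    def test_circle_temporal_pole_vertical_slope_singularity(self):
        c = EllipseSpec(0, 0, 500, 500)
        assert tangent_axis_at_point(c, (500.0, 0.0)) == pytest.approx(90.0)

    def test_ellipse_top_horizontal(self):
        c = EllipseSpec(0, 0, 2, 1)
        assert tangent_axis_at_point(c, (0.0, 1.0)) == pytest.approx(0.0)

    def test_off_conic_point_rejected(self):
        with pytest.raises(ValueError):
            tangent_axis_at_point(EllipseSpec(0, 0, 1, 1), (2.0, 2.0))

    def test_vector_form_equals_slope_formula(self):
        """The tangent direction vector reproduces the implicit-derivative
        slope -y_r^2 (x-x_c) / (x_r^2 (y-y_c)) wherever the slope is finite."""
        rng = np.random.default_rng(0)
        n = 10_000
        xc, yc = rng.uniform(-500, 500, (2, n))
        xr = rng.uniform(50, 2000, n)
        yr = rng.uniform(50, 2000, n)
        theta = rng.uniform(0, 2 * np.pi, n)
        x = xc + xr * np.cos(theta)
        y = yc + yr * np.sin(theta)
        dy = y - yc
        finite = np.abs(dy) > 1e-6
        slope = -(yr**2 * (x - xc)) / (xr**2 * dy)
        slope_axis = wrap_orientation(np.degrees(np.arctan(slope)))
        for i in np.nonzero(finite)[0][:2000]:
            axis = tangent_axis_at_point(
                EllipseSpec(xc[i], yc[i], xr[i], yr[i]), (x[i], y[i]), tol=1e-6
            )
            assert axis_difference(axis, slope_axis[i]) < 1e-6

    def test_circle_tangent_orthogonal_to_radius(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            xc, yc = rng.uniform(-1000, 1000, 2)
            r = rng.uniform(10, 2000)
            th = rng.uniform(0, 2 * np.pi)
            p = (xc + r * np.cos(th), yc + r * np.sin(th))
            axis = tangent_axis_at_point(EllipseSpec(xc, yc, r, r), p)
            radial = wrap_orientation(np.degrees(th))
            assert axis_difference(axis, radial) == pytest.approx(90.0, abs=1e-9)

    def test_family_form_matches_single_conic(self):
        rng = np.random.default_rng(2)
        anchor = (-120.0, -340.0)
        aspect = 1.3
        pts = rng.uniform(-1000, 1000, (50, 2))
        fam = tangent_axis_through_point(anchor, aspect, pts)
        for p, ax in zip(pts, fam):
            yr = np.sqrt(((p[0] - anchor[0]) / aspect) ** 2 + (p[1] - anchor[1]) ** 2)
            conic = EllipseSpec(anchor[0], anchor[1], aspect * yr, yr)
            assert axis_difference(tangent_axis_at_point(conic, p, tol=1e-9), ax) < 1e-9


class TestPredictedCurve:
    def test_origin_circles_static_45(self):
        for axis, sign in ((VN_AXIS, -1.0), (VT_AXIS, +1.0)):
            curve = predicted_angle_curve((0.0, 0.0), 1.0, axis)
            assert len(curve) == len(np.arange(100.0, 2000.0 + 1e-9, 25.0))
            assert np.allclose(curve["deviation_deg"], sign * 45.0, atol=1e-9)
            assert np.allclose(curve["distance_um"], curve["y_radius_um"])

    def test_anchor_on_axis_orthogonal_predictions(self):
        # anchor on the VT ray: every tangent is orthogonal to the ray
        anchor = (300.0, -300.0)
        curve = predicted_angle_curve(anchor, 1.0, VT_AXIS)
        ray_axis = wrap_orientation(VT_AXIS.angle_deg)
        for ax in curve["axis_deg"]:
            assert axis_difference(ax, ray_axis) == pytest.approx(90.0, abs=1e-9)

    def test_empty_sweep_errors(self):
        with pytest.raises(ValueError):
            predicted_angle_curve((0.0, 0.0), 1.0, VN_AXIS, y_radii=[])

    def test_dorsal_anchor_differs_strongly_from_ventral(self):
        ventral = predicted_angle_curve((0.0, -400.0), 1.0, VN_AXIS)
        dorsal = predicted_angle_curve((0.0, 400.0), 1.0, VN_AXIS)
        lo = max(ventral["distance_um"].min(), dorsal["distance_um"].min())
        v = ventral[ventral["distance_um"] >= lo]["deviation_deg"].mean()
        d = dorsal[dorsal["distance_um"] >= lo]["deviation_deg"].mean()
        assert abs(v - d) > 20.0


class TestQuadraticFitAndArea:
    def test_exact_quadratic_recovered(self):
        d = np.linspace(0, 10, 30)
        coeffs = fit_quadratic(d, 2.0 * d**2 - 3.0 * d + 1.0)
        assert coeffs == pytest.approx([2.0, -3.0, 1.0], abs=1e-9)

    def test_constant_data(self):
        coeffs = fit_quadratic([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
        assert coeffs[:2] == pytest.approx([0.0, 0.0], abs=1e-9)
        assert coeffs[2] == pytest.approx(5.0)

    def test_insufficient_points(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 1.0, 1.0, 2.0], [0, 0, 0, 1])

    def test_noisy_coefficients_shrink_with_n(self):
        rng = np.random.default_rng(3)
        errs = []
        for n in (20, 2000):
            d = np.linspace(0, 10, n)
            v = 0.5 * d**2 + rng.normal(0, 1.0, n)
            errs.append(abs(fit_quadratic(d, v)[0] - 0.5))
        assert errs[1] < errs[0]

    def test_area_identical_fits_zero(self):
        c = np.array([1.0, 2.0, 3.0])
        assert area_between_fits(c, c, (0.0, 100.0)) == 0.0

    def test_area_constant_offset(self):
        a = np.array([0.0, 0.0, 2.0])
        b = np.array([0.0, 0.0, 5.0])
        assert area_between_fits(a, b, (0.0, 100.0)) == pytest.approx(300.0)

    def test_area_quadratic_difference_closed_form(self):
        # |x^2| on [0, 1] integrates to 1/3
        a = np.array([1.0, 0.0, 0.0])
        b = np.zeros(3)
        assert area_between_fits(a, b, (0.0, 1.0), step_um=0.001) == pytest.approx(
            1.0 / 3.0, abs=1e-5
        )

    def test_area_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 3))
        assert area_between_fits(a, b, (0, 50)) == pytest.approx(
            area_between_fits(b, a, (0, 50))
        )

    def test_area_empty_range_errors(self):
        with pytest.raises(ValueError):
            area_between_fits(np.zeros(3), np.ones(3), (5.0, 5.0))


class TestAnchorAspectFit:
    def _measured_from_model(self, anchor, aspect):
        out = {}
        for name, axis in (("VN", VN_AXIS), ("VT", VT_AXIS)):
            curve = predicted_angle_curve(anchor, aspect, axis)
            sel = curve[(curve["distance_um"] > 600) & (curve["distance_um"] < 2000)]
            out[name] = (sel["distance_um"].to_numpy(), sel["deviation_deg"].to_numpy())
        return out

    def test_noiseless_self_consistency(self):
        """Data drawn from a known member of the search grid maps back to it."""
        truth = ((-100.0, -400.0), 1.1)
        measured = self._measured_from_model(*truth)
        fit = fit_anchor_and_aspect(
            measured,
            anchor_x_grid=np.arange(-300.0, 100.1, 100.0),
            anchor_y_grid=np.arange(-600.0, -199.9, 100.0),
            aspect_grid=np.round(np.arange(1.0, 1.21, 0.01), 10),
        )
        assert fit.anchor_xy == truth[0]
        assert fit.aspect == pytest.approx(truth[1])
        assert fit.score < 50.0  # quadratic-approximation residual only

    def test_score_surface_shape(self):
        measured = self._measured_from_model((0.0, -300.0), 1.0)
        fit = fit_anchor_and_aspect(
            measured,
            anchor_x_grid=[0.0],
            anchor_y_grid=[-300.0],
            aspect_grid=[0.9, 1.0, 1.1],
            keep_surface=True,
        )
        s = fit.surface.set_index("aspect")["score"]
        assert s[1.0] < s[0.9] and s[1.0] < s[1.1]

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            fit_anchor_and_aspect({"VN": ([1, 2, 3], [0, 0, 0])}, aspect_grid=[])


def test_invalid_ellipse_radii():
    with pytest.raises(ValueError):
        EllipseSpec(0, 0, -1.0, 1.0)
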