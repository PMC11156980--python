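"""Concentric circle/ellipse model of the orientation-preference map.

The map hypothesis: each cell's preferred orientation axis is the tangent
of the member of a family of concentric ellipses (common center = the
anchor, common x/y radius ratio = the aspect) passing through the cell's
retinal location.  For an ellipse ((x-x_c)/x_r)^2 + ((y-y_c)/y_r)^2 = 1
the tangent direction at an on-ellipse point is the vector

    ( -x_r^2 (y - y_c),  y_r^2 (x - x_c) ),

whose slope -y_r^2 (x-x_c) / (x_r^2 (y-y_c)) is the familiar implicit-
differentiation form; the vector form survives vertical tangents.

Predicted deviation-from-ventral curves are obtained by intersecting the
family with a sampling axis through the optic nerve (the ventronasal VN
and ventrotemporal VT rays, +/-45 deg from ventral), and the model is fit
to measured per-field-of-view curves by a deterministic grid search over
anchor position and aspect ratio that minimizes the summed area between
quadratic fits of the measured and modeled curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import deviation_from_ventral, unwrap_axis_deg, wrap_orientation

__all__ = [
    "EllipseSpec",
    "AxisLine",
    "VN_AXIS",
    "VT_AXIS",
    "line_conic_intersection",
    "tangent_axis_at_point",
    "tangent_axis_through_point",
    "predicted_angle_curve",
    "fit_quadratic",
    "area_between_fits",
    "FitComparison",
    "FittedMap",
    "fit_anchor_and_aspect",
]


@dataclass(frozen=True)
class EllipseSpec:
    """One conic of the family; x_radius == y_radius makes it a circle."""

    x_center: float
    y_center: float
    x_radius: float
    y_radius: float

    def __post_init__(self):
        if self.x_radius <= 0 or self.y_radius <= 0:
            raise ValueError("ellipse radii must be positive")

    @property
    def aspect(self) -> float:
        return self.x_radius / self.y_radius

    def contains_on_boundary(self, point, tol=1e-6) -> bool:
        x, y = point
        v = ((x - self.x_center) / self.x_radius) ** 2 + (
            (y - self.y_center) / self.y_radius
        ) ** 2
        return abs(v - 1.0) <= tol


@dataclass(frozen=True)
class AxisLine:
    """A sampling ray from ``origin`` (default: optic nerve) at ``angle_deg``."""

    angle_deg: float
    origin: tuple = (0.0, 0.0)

    @property
    def direction(self) -> np.ndarray:
        a = np.radians(self.angle_deg % 360.0)
        return np.array([np.cos(a), np.sin(a)])


# Ventral points straight down (-y); VN is 45 deg toward nasal (-x), VT 45 deg
# toward temporal (+x).
VN_AXIS = AxisLine(angle_deg=225.0)
VT_AXIS = AxisLine(angle_deg=315.0)


def line_conic_intersection(line: AxisLine, conic: EllipseSpec):
    """Intersection points of the full line with the conic (0, 1, or 2).

    Returns ``(points, ts)`` with ``points`` an (n, 2) array and ``ts`` the
    signed distances along the line's direction from its origin; positive t
    is the forward ray.
    """
    u = line.direction
    ox, oy = line.origin
    wx = (ox - conic.x_center) / conic.x_radius
    wy = (oy - conic.y_center) / conic.y_radius
    vx = u[0] / conic.x_radius
    vy = u[1] / conic.y_radius
    a = vx * vx + vy * vy
    b = 2.0 * (wx * vx + wy * vy)
    c = wx * wx + wy * wy - 1.0
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return np.empty((0, 2)), np.empty(0)
    sq = np.sqrt(disc)
    ts = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    if disc == 0:
        ts = ts[:1]
    pts = np.asarray(line.origin) + ts[:, None] * u
    return pts, ts


def tangent_axis_at_point(conic: EllipseSpec, point, tol=1e-6) -> float:
    """Tangent axis angle in [0, 180) at an on-conic point."""
    x, y = point
    if not conic.contains_on_boundary(point, tol=tol):
        raise ValueError(f"point {point} is not on the conic (tol={tol})")
    dx = x - conic.x_center
    dy = y - conic.y_center
    if dx == 0 and dy == 0:
        raise ValueError("point coincides with the conic center")
    tx = -(conic.x_radius**2) * dy
    ty = (conic.y_radius**2) * dx
    return float(wrap_orientation(np.degrees(np.arctan2(ty, tx))))


def tangent_axis_through_point(anchor_xy, aspect, points_xy):
    """Tangent axis of the family member through each point (vectorized).

    ``aspect`` is x_radius / y_radius, shared by all members.  Points at the
    anchor itself yield NaN.
    """
    p = np.atleast_2d(np.asarray(points_xy, dtype=float))
    dx = p[:, 0] - anchor_xy[0]
    dy = p[:, 1] - anchor_xy[1]
    # family member through p has y_radius^2 = dx^2/aspect^2 + dy^2; the
    # tangent vector (-x_r^2 dy, y_r^2 dx) reduces to (-aspect^2 dy, dx)
    tx = -(aspect**2) * dy
    ty = dx
    axes = wrap_orientation(np.degrees(np.arctan2(ty, tx)))
    axes = np.where((dx == 0) & (dy == 0), np.nan, axes)
    if np.ndim(points_xy) == 1:
        return float(axes[0])
    return axes


_DEFAULT_Y_RADII = np.arange(100.0, 2000.0 + 1e-9, 25.0)


def _predict_curve_arrays(anchor_xy, aspect, axis, y_radii, min_distance=1e-9):
    """Fast path: (y_radii, distances, points, axis angles) as plain arrays."""
    y_radii = np.asarray(y_radii, dtype=float)
    if y_radii.size == 0:
        raise ValueError("empty radius sweep")
    u = axis.direction
    ox, oy = axis.origin
    wx = ox - anchor_xy[0]
    wy = oy - anchor_xy[1]
    A2 = aspect * aspect
    # scale the ellipse equation by y_radius^2: only the constant term
    # depends on the radius, so all radii solve at once
    a = u[0] * u[0] / A2 + u[1] * u[1]
    b = 2.0 * (wx * u[0] / A2 + wy * u[1])
    c0 = wx * wx / A2 + wy * wy
    disc = b * b - 4.0 * a * (c0 - y_radii**2)
    ok = disc >= 0
    sq = np.sqrt(disc[ok])
    r_ok = y_radii[ok]
    t_lo = (-b - sq) / (2 * a)
    t_hi = (-b + sq) / (2 * a)
    ts = np.concatenate([t_lo, t_hi])
    rr = np.concatenate([r_ok, r_ok])
    fwd = ts > min_distance
    ts, rr = ts[fwd], rr[fwd]
    order = np.argsort(ts)
    ts, rr = ts[order], rr[order]
    pts = np.asarray(axis.origin) + ts[:, None] * u
    dx = pts[:, 0] - anchor_xy[0]
    dy = pts[:, 1] - anchor_xy[1]
    axes = wrap_orientation(np.degrees(np.arctan2(dx, -(A2) * dy)))
    return rr, ts, pts, axes


def predicted_angle_curve(
    anchor_xy,
    aspect,
    axis: AxisLine,
    y_radii=None,
    min_distance=1e-9,
) -> pd.DataFrame:
    """Model-predicted orientation axis along a sampling ray.

    For each generating y-radius (x-radius = aspect * y-radius), the
    forward-ray intersections with the ellipse give sampling points; at
    each, the tangent axis and its signed deviation from ventral are
    recorded against straight-line distance from the ray origin.

    Returns a DataFrame sorted by distance with columns
    ``y_radius_um, distance_um, x_um, y_um, axis_deg, deviation_deg``.
    """
    if y_radii is None:
        y_radii = _DEFAULT_Y_RADII
    rr, ts, pts, axes = _predict_curve_arrays(anchor_xy, aspect, axis, y_radii, min_distance)
    return pd.DataFrame(
        {
            "y_radius_um": rr,
            "distance_um": ts,
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "axis_deg": axes,
            "deviation_deg": deviation_from_ventral(axes),
        }
    )


def fit_quadratic(distances, values):
    """Least-squares degree-2 polynomial coefficients (numpy order, highest first)."""
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.unique(d).size < 3:
        raise ValueError("quadratic fit needs >= 3 distinct distances")
    return np.polyfit(d, v, 2)


@dataclass
class FitComparison:
    """Quadratic fits of a measured and a modeled curve plus their gap."""

    coeffs_data: np.ndarray
    coeffs_model: np.ndarray
    d_range: tuple
    area_between: float  # degrees * micrometers over d_range


def area_between_fits(coeffs_a, coeffs_b, d_range, step_um=1.0) -> float:
    """∫ |q_a(d) − q_b(d)| dd over ``d_range`` by trapezoid on a fine grid."""
    lo, hi = d_range
    if hi <= lo:
        raise ValueError("empty distance range")
    grid = np.arange(lo, hi + step_um / 2, step_um)
    diff = np.abs(np.polyval(coeffs_a, grid) - np.polyval(coeffs_b, grid))
    return float(np.trapezoid(diff, grid))


@dataclass
class FittedMap:
    """Result of the anchor/aspect grid search."""

    anchor_xy: tuple
    aspect: float
    score: float  # summed area-between across axes
    comparisons: dict = field(default_factory=dict)  # axis name -> FitComparison
    surface: pd.DataFrame | None = None  # full (x, y, aspect, score) grid


def fit_anchor_and_aspect(
    measured,
    axes=None,
    anchor_x_grid=None,
    anchor_y_grid=None,
    aspect_grid=None,
    y_radii=None,
    keep_surface=True,
) -> FittedMap:
    """Deterministic grid search for the map anchor and aspect ratio.

    Parameters
    ----------
    measured : dict mapping axis name -> (distances_um, deviations_deg)
        Per-axis measured deviation-from-ventral vs distance points
        (typically one point per field of view).
    axes : dict mapping the same names -> AxisLine (default VN/VT).

    Each candidate (anchor, aspect) is scored by the summed
    :func:`area_between_fits` between the quadratic fit of the measured
    points and the quadratic fit of the model's predicted curve, over each
    axis's shared distance range.  Candidates whose model curve is
    degenerate on any axis score infinity.
    """
    if axes is None:
        axes = {"VN": VN_AXIS, "VT": VT_AXIS}
    if anchor_x_grid is None:
        anchor_x_grid = np.arange(-600.0, 600.0 + 1e-9, 100.0)
    if anchor_y_grid is None:
        anchor_y_grid = np.arange(-1200.0, 0.0 + 1e-9, 100.0)
    if aspect_grid is None:
        aspect_grid = np.round(np.arange(0.95, 1.25 + 1e-9, 0.01), 10)
    if len(anchor_x_grid) == 0 or len(anchor_y_grid) == 0 or len(aspect_grid) == 0:
        raise ValueError("empty search grid")

    data_fit = {}
    data_range = {}
    for name, (d, dev) in measured.items():
        order = np.argsort(np.asarray(d, dtype=float))
        d_s = np.asarray(d, dtype=float)[order]
        dev_s = unwrap_axis_deg(np.asarray(dev, dtype=float)[order])
        data_fit[name] = fit_quadratic(d_s, dev_s)
        data_range[name] = (float(d_s.min()), float(d_s.max()))

    if y_radii is None:
        y_radii = _DEFAULT_Y_RADII
    rows = []
    best = None
    for ax_c, ay_c, asp in itertools.product(anchor_x_grid, anchor_y_grid, aspect_grid):
        score = 0.0
        comps = {}
        for name, axis in axes.items():
            _, ts, _, ax_angles = _predict_curve_arrays((ax_c, ay_c), asp, axis, y_radii)
            # the model quadratic describes the curve where data exist; points
            # outside the measured distance range (e.g. the near-tangency
            # branch close to the anchor) must not distort the fit
            in_range = (ts >= data_range[name][0]) & (ts <= data_range[name][1])
            ts, ax_angles = ts[in_range], ax_angles[in_range]
            if np.unique(ts).size < 3:
                score = np.inf
                break
            lo = max(data_range[name][0], float(ts.min()))
            hi = min(data_range[name][1], float(ts.max()))
            if hi <= lo:
                score = np.inf
                break
            dev = unwrap_axis_deg(deviation_from_ventral(ax_angles))
            cm = np.polyfit(ts, dev, 2)
            area = area_between_fits(data_fit[name], cm, (lo, hi))
            comps[name] = FitComparison(data_fit[name], cm, (lo, hi), area)
            score += area
        if keep_surface:
            rows.append((ax_c, ay_c, asp, score))
        if best is None or score < best[0]:
            best = (score, (float(ax_c), float(ay_c)), float(asp), comps)

    surface = (
        pd.DataFrame(rows, columns=["anchor_x_um", "anchor_y_um", "aspect", "score"])
        if keep_surface
        else None
    )
    score, anchor, asp, comps = best
    return FittedMap(anchor_xy=anchor, aspect=asp, score=score, comparisons=comps, surface=surface)
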