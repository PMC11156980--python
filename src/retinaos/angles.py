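"""Angle conventions and circular helpers.

All geometry uses a retina-fixed frame: origin at the optic nerve head,
+x temporal, +y dorsal, angles counter-clockwise from +x in degrees.
Motion directions live on [0, 360); orientation axes on [0, 180) (an axis
and its 180 deg flip are the same stimulus axis).  The ventral cardinal
axis is the vertical 90 deg axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_direction",
    "wrap_orientation",
    "deviation_from_ventral",
    "axis_from_deviation",
    "circular_mean_axis",
    "unwrap_axis_deg",
    "axis_difference",
]


def wrap_direction(deg):
    """Map direction angles into [0, 360)."""
    # double modulo: x % 360 can round to exactly 360.0 for tiny negative x
    return (np.asarray(deg, dtype=float) % 360.0) % 360.0


def wrap_orientation(deg):
    """Map axis angles into [0, 180); 180.0 wraps to 0.0."""
    return (np.asarray(deg, dtype=float) % 180.0) % 180.0


def deviation_from_ventral(axis_deg):
    """Signed deviation of an orientation axis from the ventral (vertical) axis.

    Returns values in (-90, 90]: 0 for the vertical axis, +90 for the
    horizontal axis (boundary convention), positive for axes tilted toward
    temporal (+x) retina.  Scalar in, scalar out.
    """
    axis = np.asarray(axis_deg, dtype=float)
    dev = (90.0 - axis) % 180.0
    dev = np.where(dev > 90.0, dev - 180.0, dev)
    if np.ndim(axis_deg) == 0:
        return float(dev)
    return dev


def axis_from_deviation(dev_deg):
    """Inverse of :func:`deviation_from_ventral` (axis in [0, 180))."""
    axis = (90.0 - np.asarray(dev_deg, dtype=float)) % 180.0
    if np.ndim(dev_deg) == 0:
        return float(axis)
    return axis


def circular_mean_axis(axes_deg, weights=None):
    """Double-angle circular mean of orientation axes.

    Returns ``(mean_axis_deg, resultant_length)``.  The resultant length is
    1 for identical axes and 0 for a balanced orthogonal mixture; callers
    should treat the mean as undefined when the resultant is small.
    """
    a = np.radians(2.0 * np.asarray(axes_deg, dtype=float))
    if a.size == 0:
        return float("nan"), 0.0
    if weights is None:
        z = np.exp(1j * a).mean()
    else:
        w = np.asarray(weights, dtype=float)
        z = (w * np.exp(1j * a)).sum() / w.sum()
    mean_axis = wrap_orientation(np.degrees(np.angle(z)) / 2.0)
    return float(mean_axis), float(np.abs(z))


def unwrap_axis_deg(values_deg):
    """Unwrap a sequence of axis-valued angles (period 180) into a continuous branch."""
    v = np.asarray(values_deg, dtype=float)
    return np.degrees(np.unwrap(np.radians(2.0 * v))) / 2.0


def axis_difference(a_deg, b_deg):
    """Smallest absolute difference between two orientation axes, in [0, 90]."""
    d = np.abs((np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0)
    d = np.minimum(d, 180.0 - d)
    if np.ndim(a_deg) == 0 and np.ndim(b_deg) == 0:
        return float(d)
    return d
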