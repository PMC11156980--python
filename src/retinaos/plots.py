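"""Optional figure rendering (tables are the primary outputs)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .retinamap import orientation_histogram

__all__ = ["plot_polar_histogram", "plot_flow_field", "plot_model_vs_data"]


def plot_polar_histogram(angles_deg, bin_deg=10.0, path=None, title=""):
    """Polar histogram with each axis duplicated at φ and φ+180."""
    counts, edges = orientation_histogram(angles_deg, bin_deg, polar=True)
    centers = np.radians((edges[:-1] + edges[1:]) / 2)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.bar(centers, counts, width=np.radians(bin_deg), alpha=0.7)
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_flow_field(ff, path=None, scale=40.0):
    """Quiver-style rendering of a flow-field table (axes drawn as bars)."""
    fig, ax = plt.subplots()
    ok = ff["mean_axis_deg"].notna()
    a = np.radians(ff.loc[ok, "mean_axis_deg"])
    u = np.cos(a) * scale * ff.loc[ok, "resultant"]
    v = np.sin(a) * scale * ff.loc[ok, "resultant"]
    x, y = ff.loc[ok, "bin_x_um"], ff.loc[ok, "bin_y_um"]
    ax.plot([x - u, x + u], [y - v, y + v], color="m", lw=1.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm, temporal →)")
    ax.set_ylabel("y (µm, dorsal →)")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_model_vs_data(measured_d, measured_dev, comparison, path=None, title=""):
    """Measured points, both quadratic fits, and the shaded area between them."""
    fig, ax = plt.subplots()
    ax.plot(measured_d, measured_dev, "ko", ms=4, label="data")
    lo, hi = comparison.d_range
    grid = np.linspace(lo, hi, 200)
    qa = np.polyval(comparison.coeffs_data, grid)
    qm = np.polyval(comparison.coeffs_model, grid)
    ax.plot(grid, qa, "k-", label="data fit")
    ax.plot(grid, qm, "r-", label="model")
    ax.fill_between(grid, qa, qm, color="r", alpha=0.2)
    ax.set_xlabel("distance from optic nerve (µm)")
    ax.set_ylabel("deviation from ventral (deg)")
    ax.set_title(title)
    ax.legend()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
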