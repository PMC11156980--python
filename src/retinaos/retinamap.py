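"""Map-level statistics of preferred orientation across the retina.

Cells and fields of view (FOVs) carry coordinates in micrometers relative
to the optic nerve (+x temporal, +y dorsal).  This module aggregates
preferred-orientation axes into histograms per retinal region, signed
deviation-from-ventral curves against distance from the optic nerve,
coarse vector flow fields (double-angle circular means on a spatial
grid), and two-sample comparisons of deviation distributions between
regions (Kolmogorov–Smirnov plus a label-permutation test on the KS D
statistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .angles import circular_mean_axis, deviation_from_ventral, wrap_orientation

__all__ = [
    "orientation_histogram",
    "deviation_from_ventral",
    "deviation_vs_distance",
    "flow_field",
    "DistributionComparison",
    "compare_regions",
]

logger = logging.getLogger(__name__)

#: below this double-angle resultant length a bin's mean axis is undefined
MIN_RESULTANT = 0.1


def orientation_histogram(angles_deg, bin_deg: float = 10.0, polar: bool = False):
    """Histogram of orientation axes over [0, 180).

    Returns ``(counts, bin_edges)``.  With ``polar=True`` the axes are
    duplicated at φ and φ+180 over [0, 360) bins, for display symmetry on a
    polar plot.  Empty input yields all-zero counts.
    """
    angles = wrap_orientation(np.asarray(angles_deg, dtype=float).ravel())
    span = 360.0 if polar else 180.0
    edges = np.arange(0.0, span + bin_deg / 2, bin_deg)
    if polar:
        angles = np.concatenate([angles, angles + 180.0])
    counts, edges = np.histogram(angles, bins=edges)
    return counts, edges


def deviation_vs_distance(cells: pd.DataFrame, fovs: pd.DataFrame, group: str | None = "overrepresented"):
    """Per-FOV deviation-from-ventral of the mean preferred axis vs distance.

    ``cells`` needs columns fov_id, pref_orientation_deg and (when
    ``group`` is given) orientation_group.  Returns a DataFrame with one
    row per FOV holding the FOV's distance from the optic nerve, the
    double-angle circular mean deviation, the resultant length, and the
    cell count; FOVs without qualifying cells are skipped with a log
    entry.
    """
    sel = cells
    if group is not None:
        sel = cells[cells["orientation_group"] == group]
    rows = []
    for _, fov in fovs.iterrows():
        sub = sel[sel["fov_id"] == fov["fov_id"]]
        if len(sub) == 0:
            logger.info("FOV %s skipped: no qualifying OS cells", fov["fov_id"])
            continue
        mean_axis, res = circular_mean_axis(sub["pref_orientation_deg"])
        rows.append(
            {
                "fov_id": fov["fov_id"],
                "quadrant": fov.get("quadrant", ""),
                "distance_um": float(fov["distance_um"]),
                "n_cells": len(sub),
                "mean_axis_deg": mean_axis,
                "mean_deviation_deg": deviation_from_ventral(mean_axis),
                "resultant": res,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fov_id",
            "quadrant",
            "distance_um",
            "n_cells",
            "mean_axis_deg",
            "mean_deviation_deg",
            "resultant",
        ],
    )


def flow_field(
    cells: pd.DataFrame,
    grid_um: float = 100.0,
    min_n: int = 5,
    min_resultant: float = MIN_RESULTANT,
) -> pd.DataFrame:
    """Vector flow field: double-angle circular mean axis on a spatial grid.

    Bins with fewer than ``min_n`` cells are dropped; bins whose resultant
    length falls below ``min_resultant`` keep their coherence but report an
    undefined (NaN) mean axis.  Columns: bin_x_um, bin_y_um (bin centers),
    n_cells, mean_axis_deg, resultant.
    """
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    phi = cells["pref_orientation_deg"].to_numpy(dtype=float)
    ix = np.floor(x / grid_um).astype(int)
    iy = np.floor(y / grid_um).astype(int)
    rows = []
    for (bx, by) in sorted(set(zip(ix, iy))):
        m = (ix == bx) & (iy == by)
        if m.sum() < min_n:
            continue
        mean_axis, res = circular_mean_axis(phi[m])
        rows.append(
            {
                "bin_x_um": (bx + 0.5) * grid_um,
                "bin_y_um": (by + 0.5) * grid_um,
                "n_cells": int(m.sum()),
                "mean_axis_deg": mean_axis if res >= min_resultant else np.nan,
                "resultant": res,
            }
        )
    return pd.DataFrame(
        rows, columns=["bin_x_um", "bin_y_um", "n_cells", "mean_axis_deg", "resultant"]
    )


@dataclass
class DistributionComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    ks_statistic: float
    ks_p: float
    perm_p: float
    n_perm: int


def compare_regions(
    deviations_a,
    deviations_b,
    names=("a", "b"),
    n_perm: int = 10_000,
    rng=None,
) -> DistributionComparison:
    """Two-sample comparison of deviation distributions.

    KS test (scipy) plus a label-permutation p-value using KS D as the
    permuted statistic, with the add-one correction (1 + #{D_perm >= D}) /
    (1 + n_perm).
    """
    a = np.asarray(deviations_a, dtype=float)
    b = np.asarray(deviations_b, dtype=float)
    if a.size == 0 or b.size == 0:
        empty = names[0] if a.size == 0 else names[1]
        raise ValueError(f"region group {empty!r} is empty")
    if rng is None:
        rng = np.random.default_rng()
    ks = ks_2samp(a, b)
    pool = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        d = ks_2samp(perm[: a.size], perm[a.size :]).statistic
        if d >= ks.statistic:
            count += 1
    return DistributionComparison(
        group_a=names[0],
        group_b=names[1],
        n_a=a.size,
        n_b=b.size,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        perm_p=(1 + count) / (1 + n_perm),
        n_perm=n_perm,
    )
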