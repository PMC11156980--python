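"""Functional subtyping of OS cells by k-means + silhouette analysis.

Two feature spaces are used, following the study design:

* the ON-OFF response shape — the trial- and direction-averaged ΔF/F
  trace cropped to the light-onset and post-offset windows, resampled to a
  fixed length and peak-normalized; and
* the preferred orientation — embedded as the double-angle unit vector
  (cos 2φ, sin 2φ) so that 0° and 180° coincide and orthogonal axes are
  antipodal.

K-means is run for k = 2..10 (best of several restarts) and the solution
with the highest mean silhouette value SV(i) = (b(i) − a(i)) / max(a(i),
b(i)) is kept, where a(i) is the mean distance of point i to its own
cluster and b(i) the mean distance to the nearest other cluster.  A
permuted-data control (each feature dimension shuffled independently
across cells) reports the silhouette curve expected from structureless
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

__all__ = [
    "FeatureMeta",
    "ClusterSolution",
    "extract_onoff_features",
    "orientation_features",
    "silhouette_values",
    "cluster_and_select_k",
    "label_subtypes",
    "cluster_axis_angles",
]


@dataclass(frozen=True)
class FeatureMeta:
    """Layout of a resampled ON-OFF feature vector."""

    n_on: int    # samples covering the stimulus-on window
    n_off: int   # samples covering the post-offset window

    @property
    def length(self) -> int:
        return self.n_on + self.n_off


@dataclass
class ClusterSolution:
    k_range: tuple
    mean_sv: dict            # k -> mean silhouette of the best k-means run
    labels_by_k: dict        # k -> label array
    chosen_k: int
    labels: np.ndarray       # labels at chosen_k
    sv_per_cell: np.ndarray  # silhouettes at chosen_k
    permuted_mean_sv: dict = field(default_factory=dict)

    def curve(self) -> pd.DataFrame:
        ks = sorted(self.mean_sv)
        return pd.DataFrame(
            {
                "k": ks,
                "mean_sv": [self.mean_sv[k] for k in ks],
                "permuted_mean_sv": [self.permuted_mean_sv.get(k, np.nan) for k in ks],
            }
        )


def extract_onoff_features(rm_stack, proto, n_on=24, n_off=16):
    """ON-OFF response features for a (n_cells, k, T, R) ΔF/F stack.

    The trace is averaged over repetitions and directions, cropped to the
    stimulus-on and post-offset windows, linearly resampled to ``n_on`` +
    ``n_off`` points, and normalized by its peak absolute value; cells
    whose averaged trace is identically zero are flagged degenerate and
    left unnormalized.

    Returns ``(features, meta, degenerate_mask)``.
    """
    rm_stack = np.asarray(rm_stack, dtype=float)
    mean_trace = rm_stack.mean(axis=(1, 3))  # (n_cells, T)
    segments = []
    for (lo, hi), n_out in ((proto.stim_on_window, n_on), (proto.post_off_window, n_off)):
        seg = mean_trace[:, lo:hi]
        src = np.arange(seg.shape[1], dtype=float)
        dst = np.linspace(0.0, seg.shape[1] - 1.0, n_out)
        segments.append(
            np.stack([np.interp(dst, src, row) for row in seg])
        )
    feats = np.concatenate(segments, axis=1)
    peak = np.abs(feats).max(axis=1)
    degenerate = peak == 0.0
    feats = feats / np.where(degenerate, 1.0, peak)[:, None]
    return feats, FeatureMeta(n_on=n_on, n_off=n_off), degenerate


def orientation_features(pref_orientation_deg):
    """Double-angle unit-vector embedding (cos 2φ, sin 2φ) of axes."""
    phi = np.radians(2.0 * np.asarray(pref_orientation_deg, dtype=float))
    return np.column_stack([np.cos(phi), np.sin(phi)])


def silhouette_values(points, labels):
    """Per-point silhouette values and their mean, Euclidean metric.

    Singleton clusters get SV = 0 (standard convention); so do points with
    a(i) = b(i) = 0.  Requires at least two nonempty clusters.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette analysis requires k >= 2 nonempty clusters")
    D = squareform(pdist(X))
    n = len(X)
    sv = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            sv[i] = 0.0
            continue
        a = D[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(D[i, masks[o]].mean() for o in uniq if o != c)
        m = max(a, b)
        sv[i] = 0.0 if m == 0 else (b - a) / m
    return sv, float(sv.mean())


def _permute_columns(X, rng):
    Xp = np.empty_like(X)
    for j in range(X.shape[1]):
        Xp[:, j] = rng.permutation(X[:, j])
    return Xp


def cluster_and_select_k(
    features,
    k_range=range(2, 11),
    restarts: int = 10,
    seed: int = 0,
    permuted_control: bool = True,
) -> ClusterSolution:
    """Best-of-restarts k-means over ``k_range``; keep the k with highest mean SV."""
    X = np.asarray(features, dtype=float)
    k_range = tuple(k_range)
    if len(X) < max(k_range) + 1:
        raise ValueError(f"need at least {max(k_range) + 1} points for k up to {max(k_range)}")
    if np.allclose(X, X[0]):
        raise ValueError("all feature vectors identical; clustering is degenerate")

    def sweep(Xs, base_seed):
        mean_sv, labels_by_k = {}, {}
        for k in k_range:
            km = KMeans(n_clusters=k, n_init=restarts, random_state=base_seed + k)
            lab = km.fit_predict(Xs)
            _, m = silhouette_values(Xs, lab)
            mean_sv[k] = m
            labels_by_k[k] = lab
        return mean_sv, labels_by_k

    mean_sv, labels_by_k = sweep(X, seed)
    chosen_k = max(mean_sv, key=mean_sv.get)
    sv, _ = silhouette_values(X, labels_by_k[chosen_k])

    permuted = {}
    if permuted_control:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
        permuted, _ = sweep(_permute_columns(X, rng), seed + 10_000)

    return ClusterSolution(
        k_range=k_range,
        mean_sv=mean_sv,
        labels_by_k=labels_by_k,
        chosen_k=chosen_k,
        labels=labels_by_k[chosen_k],
        sv_per_cell=sv,
        permuted_mean_sv=permuted,
    )


def label_subtypes(
    solution: ClusterSolution,
    features,
    meta: FeatureMeta,
    sustained_threshold: float = 0.4,
    min_peak: float = 0.1,
):
    """Name clusters ONs / ONt / OFF by matching centroid kinetics.

    A centroid whose post-offset peak exceeds its onset-window peak is OFF.
    ON centroids are sustained (ONs) when the response at the end of the
    stimulus window retains at least ``sustained_threshold`` of the onset
    peak, transient (ONt) otherwise.  Centroids with no clear response
    (peak below ``min_peak``) are labeled "unassigned" rather than silently
    misnamed.

    Returns an array of subtype names per cell.
    """
    X = np.asarray(features, dtype=float)
    names = {}
    for c in np.unique(solution.labels):
        cen = X[solution.labels == c].mean(axis=0)
        on, off = cen[: meta.n_on], cen[meta.n_on :]
        on_peak, off_peak = on.max(), off.max()
        if max(on_peak, off_peak) < min_peak:
            names[c] = "unassigned"
        elif off_peak > on_peak:
            names[c] = "OFF"
        elif on[-1] >= sustained_threshold * on_peak:
            names[c] = "ONs"
        else:
            names[c] = "ONt"
    return np.array([names[c] for c in solution.labels])


def assign_orientation_groups(pref_orientation_deg, fov_ids):
    """Over- vs under-represented group per cell, relative to the local map.

    Because the overrepresented axis varies across the retina, group
    membership is defined locally: within each FOV the double-angle
    circular mean axis (dominated by the majority group, whose antipodal
    minority only shortens the resultant) is the local overrepresented
    axis; cells more than 45 deg from it belong to the orthogonal
    underrepresented group.
    """
    from .angles import axis_difference, circular_mean_axis

    phi = np.asarray(pref_orientation_deg, dtype=float)
    fov_ids = np.asarray(fov_ids)
    out = np.empty(len(phi), dtype=object)
    for f in np.unique(fov_ids):
        m = fov_ids == f
        local_axis, _ = circular_mean_axis(phi[m])
        out[m] = np.where(
            axis_difference(phi[m], local_axis) <= 45.0,
            "overrepresented",
            "underrepresented",
        )
    return out.astype(str)


def cluster_axis_angles(labels, pref_orientation_deg):
    """Double-angle circular mean axis per cluster; dict label -> degrees."""
    from .angles import circular_mean_axis

    out = {}
    for c in np.unique(labels):
        ax, _ = circular_mean_axis(np.asarray(pref_orientation_deg)[labels == c])
        out[c] = ax
    return out
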