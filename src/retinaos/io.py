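"""Table and container I/O with strict schemas.

CSV tables are UTF-8 with '.' decimals and documented headers; orientation
columns are normalized into [0, 180) on read (180.0 wraps to 0.0 with a
warning).  Response stacks live in an HDF5 container with one group per
cell and one T x R dataset per direction::

    /cells/<cell_id>/dir_<angle>   float64 (T, R)

with the stimulus protocol stored in root attributes.
"""

from __future__ import annotations

import warnings

import h5py
import numpy as np
import pandas as pd

from .responses import StimulusProtocol

__all__ = [
    "CELL_COLUMNS",
    "FOV_COLUMNS",
    "SchemaError",
    "validate_columns",
    "write_cells_csv",
    "read_cells_csv",
    "write_fovs_csv",
    "read_fovs_csv",
    "write_responses_h5",
    "read_responses_h5",
]

CELL_COLUMNS = [
    "cell_id",
    "fov_id",
    "x_um",
    "y_um",
    "selectivity_class",
    "subtype",
    "orientation_group",
    "true_pref_orientation_deg",
    "true_pref_direction_deg",
    "true_tuning_strength",
    "ds_modulation",
    "kinetic_template",
]

FOV_COLUMNS = ["fov_id", "center_x_um", "center_y_um", "quadrant", "distance_um"]

ORIENTATION_COLUMNS = (
    "true_pref_orientation_deg",
    "pref_orientation_deg",
    "pref_orientation_sampled_deg",
    "mean_axis_deg",
)


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def validate_columns(df: pd.DataFrame, required, name: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")


def _normalize_orientations(df: pd.DataFrame) -> pd.DataFrame:
    for col in ORIENTATION_COLUMNS:
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            bad = np.isfinite(vals) & ((vals >= 180.0) | (vals < 0.0))
            if bad.any():
                warnings.warn(
                    f"{bad.sum()} value(s) in {col!r} outside [0, 180); normalized",
                    stacklevel=3,
                )
                df = df.copy()
                df[col] = np.where(np.isfinite(vals), vals % 180.0, vals)
    return df


def write_cells_csv(cells: pd.DataFrame, path):
    validate_columns(cells, ["cell_id", "fov_id", "x_um", "y_um"], "cell")
    cells.to_csv(path, index=False)


def read_cells_csv(path, required=None) -> pd.DataFrame:
    # 'n/a' is a real category level (not-applicable subtype), not missing data
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    validate_columns(df, required if required is not None else ["cell_id", "fov_id", "x_um", "y_um"], "cell")
    return _normalize_orientations(df)


def write_fovs_csv(fovs: pd.DataFrame, path):
    validate_columns(fovs, FOV_COLUMNS, "fov")
    fovs.to_csv(path, index=False)


def read_fovs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_columns(df, FOV_COLUMNS, "fov")
    return df


def write_responses_h5(path, responses, cell_ids, proto: StimulusProtocol):
    """Write a (n_cells, k, T, R) stack into the per-cell HDF5 layout."""
    responses = np.asarray(responses, dtype=float)
    with h5py.File(path, "w") as f:
        f.attrs["direction_angles_deg"] = list(proto.direction_angles_deg)
        f.attrs["n_reps"] = proto.n_reps
        f.attrs["frames_per_trial"] = proto.frames_per_trial
        f.attrs["frame_rate_hz"] = proto.frame_rate_hz
        f.attrs["stim_on_window"] = list(proto.stim_on_window)
        f.attrs["post_off_window"] = list(proto.post_off_window)
        grp = f.create_group("cells")
        for rm, cid in zip(responses, cell_ids):
            g = grp.create_group(str(int(cid)))
            for a, mat in zip(proto.direction_angles_deg, rm):
                g.create_dataset(f"dir_{int(round(a)):03d}", data=mat)


def read_responses_h5(path):
    """Read the container back; returns ``(responses, cell_ids, protocol)``."""
    with h5py.File(path, "r") as f:
        proto = StimulusProtocol(
            direction_angles_deg=tuple(float(a) for a in f.attrs["direction_angles_deg"]),
            n_reps=int(f.attrs["n_reps"]),
            frames_per_trial=int(f.attrs["frames_per_trial"]),
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            stim_on_window=tuple(int(v) for v in f.attrs["stim_on_window"]),
            post_off_window=tuple(int(v) for v in f.attrs["post_off_window"]),
        )
        grp = f["cells"]
        cell_ids = sorted(grp.keys(), key=int)
        out = np.empty(
            (len(cell_ids), proto.n_directions, proto.frames_per_trial, proto.n_reps)
        )
        for i, cid in enumerate(cell_ids):
            g = grp[cid]
            for j, a in enumerate(proto.direction_angles_deg):
                out[i, j] = g[f"dir_{int(round(a)):03d}"][()]
    return out, np.array([int(c) for c in cell_ids]), proto
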