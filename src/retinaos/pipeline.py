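"""End-to-end orchestration: simulate → tune → classify → cluster → map → fit-model.

Every stage reads the previous stage's declared files from the output
directory and appends its own; ``manifest.json`` records the package
version, seed, parameters, and per-stage output row counts.  All stages
are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .angles import deviation_from_ventral
from .clustering import (
    assign_orientation_groups,
    cluster_and_select_k,
    extract_onoff_features,
    label_subtypes,
    orientation_features,
)
from .concentric import fit_anchor_and_aspect
from .responses import summarize_cell
from .retinamap import compare_regions, deviation_vs_distance, flow_field, orientation_histogram
from .significance import quality_filter, run_significance
from .synthetic import RetinaModelConfig, generate_retina, synthesize_responses

logger = logging.getLogger(__name__)

STAGES = ("simulate", "tune", "classify", "cluster", "map", "fit-model")


class MissingStageError(RuntimeError):
    """A stage's upstream outputs are absent."""


@dataclass
class PipelineConfig:
    retina: RetinaModelConfig = field(default_factory=RetinaModelConfig)
    qi_threshold: float = 0.6
    n_perms: int = 1000
    k_range: tuple = tuple(range(2, 11))
    cluster_restarts: int = 10
    histogram_bin_deg: float = 10.0
    flow_grid_um: float = 100.0
    flow_min_n: int = 5
    region_n_perm: int = 2000
    ventral_split_um: float = 400.0
    model_anchor_x: tuple = (-600.0, 600.0, 100.0)   # lo, hi, step
    model_anchor_y: tuple = (-1200.0, 0.0, 100.0)
    model_aspect: tuple = (0.95, 1.25, 0.01)
    model_radii: tuple = (100.0, 2000.0, 25.0)
    seed: int = 0
    outdir: str = "retinaos_out"

    def __post_init__(self):
        if isinstance(self.retina, dict):
            self.retina = RetinaModelConfig(**self.retina)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        for key in ("k_range",):
            if key in data:
                data[key] = tuple(data[key])
        if "retina" in data:
            for key in (
                "subtype_mix",
                "subtype_tuning_kappa",
                "map_anchor_xy_um",
                "quadrants",
                "stim_on_window",
                "post_off_window",
            ):
                if key in data["retina"]:
                    data["retina"][key] = tuple(data["retina"][key])
        return cls(**data)

    def to_yaml(self, path):
        data = dataclasses.asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(data, f, sort_keys=False)

    def grid(self, spec):
        lo, hi, step = spec
        return np.round(np.arange(lo, hi + step / 2, step), 10)


def _out(config) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise MissingStageError(
            f"stage '{needed_by}' needs {path.name}, produced by stage '{stage}'; "
            f"run '{stage}' first"
        )
    return path


def _manifest_update(outdir: Path, stage: str, entries: dict, config: PipelineConfig):
    from . import __version__

    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    manifest["stages"][stage] = entries
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def stage_simulate(config: PipelineConfig):
    out = _out(config)
    retina = dataclasses.replace(config.retina, seed=config.seed)
    cells, fovs = generate_retina(retina)
    responses = synthesize_responses(cells, retina)
    rio.write_cells_csv(cells, out / "cells.csv")
    rio.write_fovs_csv(fovs, out / "fovs.csv")
    rio.write_responses_h5(out / "responses.h5", responses, cells["cell_id"], retina.protocol())
    _manifest_update(
        out,
        "simulate",
        {"cells.csv": len(cells), "fovs.csv": len(fovs), "responses.h5": len(cells)},
        config,
    )
    return cells, fovs, responses


def stage_tune(config: PipelineConfig):
    out = _out(config)
    _require(out / "responses.h5", "simulate", "tune")
    responses, cell_ids, proto = rio.read_responses_h5(out / "responses.h5")
    rows = []
    for rm, cid in zip(responses, cell_ids):
        d = summarize_cell(rm, proto).as_dict()
        d["cell_id"] = cid
        rows.append(d)
    tuning = pd.DataFrame(rows)
    tuning.to_csv(out / "tuning.csv", index=False)
    _manifest_update(out, "tune", {"tuning.csv": len(tuning)}, config)
    return tuning


def stage_classify(config: PipelineConfig):
    out = _out(config)
    _require(out / "responses.h5", "simulate", "classify")
    _require(out / "tuning.csv", "tune", "classify")
    responses, cell_ids, proto = rio.read_responses_h5(out / "responses.h5")
    tuning = pd.read_csv(out / "tuning.csv")
    passed, counts = quality_filter(tuning, config.qi_threshold)
    keep = np.isin(cell_ids, passed["cell_id"].to_numpy())
    sig = run_significance(
        responses[keep], proto, cell_ids[keep], seed=config.seed, n_perms=config.n_perms
    )
    merged = tuning.merge(sig, on="cell_id", how="left")
    merged["qi_passed"] = merged["cell_id"].isin(passed["cell_id"])
    merged["measured_class"] = merged["measured_class"].fillna("excluded")
    merged.to_csv(out / "classified.csv", index=False)
    class_counts = merged["measured_class"].value_counts().to_dict()
    n_classified = int(merged["qi_passed"].sum())
    summary = {
        "qi_threshold": config.qi_threshold,
        "qi_retained": counts["retained"],
        "qi_dropped": counts["dropped"],
        "class_counts": class_counts,
        "class_fractions": {
            k: v / n_classified for k, v in class_counts.items() if k != "excluded"
        },
    }
    (out / "class_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _manifest_update(out, "classify", {"classified.csv": len(merged)}, config)
    return merged, summary


def stage_cluster(config: PipelineConfig):
    out = _out(config)
    _require(out / "responses.h5", "simulate", "cluster")
    _require(out / "classified.csv", "classify", "cluster")
    responses, cell_ids, proto = rio.read_responses_h5(out / "responses.h5")
    classified = pd.read_csv(out / "classified.csv")
    os_mask = classified["measured_class"].isin(["OS", "both"]).to_numpy()
    os_ids = classified.loc[os_mask, "cell_id"].to_numpy()
    keep = np.isin(cell_ids, os_ids)

    feats, meta, _ = extract_onoff_features(responses[keep], proto)
    sol = cluster_and_select_k(
        feats, config.k_range, restarts=config.cluster_restarts, seed=config.seed
    )
    subtype = label_subtypes(sol, feats, meta)

    _require(out / "cells.csv", "simulate", "cluster")
    cells = rio.read_cells_csv(out / "cells.csv")
    idx = classified.set_index("cell_id")
    ori = idx.loc[cell_ids[keep], "pref_orientation_deg"].to_numpy()
    fov_of = cells.set_index("cell_id").loc[cell_ids[keep], "fov_id"].to_numpy()
    group = assign_orientation_groups(ori, fov_of)
    # silhouette analysis of preferred orientation, measured relative to the
    # local (per-FOV) mean axis so the map's spatial drift does not smear
    # the orthogonal-axes bimodality
    from .angles import circular_mean_axis

    rel = np.empty(len(ori))
    for f in np.unique(fov_of):
        m = fov_of == f
        local_axis, _ = circular_mean_axis(ori[m])
        rel[m] = (ori[m] - local_axis) % 180.0
    ofeats = orientation_features(rel)
    osol = cluster_and_select_k(
        ofeats, config.k_range, restarts=config.cluster_restarts, seed=config.seed + 1
    )

    sub_df = pd.DataFrame(
        {
            "cell_id": cell_ids[keep],
            "measured_subtype": subtype,
            "measured_orientation_group": group,
        }
    )
    merged = classified.merge(sub_df, on="cell_id", how="left")
    merged.to_csv(out / "classified.csv", index=False)
    curve = sol.curve()
    curve["feature_space"] = "onoff"
    ocurve = osol.curve()
    ocurve["feature_space"] = "orientation"
    pd.concat([curve, ocurve]).to_csv(out / "silhouette_curve.csv", index=False)
    _manifest_update(
        out,
        "cluster",
        {
            "classified.csv": len(merged),
            "silhouette_curve.csv": len(curve) + len(ocurve),
            "chosen_k_onoff": int(sol.chosen_k),
            "chosen_k_orientation": int(osol.chosen_k),
        },
        config,
    )
    return merged, sol, osol


def stage_map(config: PipelineConfig):
    out = _out(config)
    _require(out / "classified.csv", "classify", "map")
    _require(out / "cells.csv", "simulate", "map")
    _require(out / "fovs.csv", "simulate", "map")
    classified = pd.read_csv(out / "classified.csv")
    cells = rio.read_cells_csv(out / "cells.csv")
    fovs = rio.read_fovs_csv(out / "fovs.csv")
    df = classified.merge(cells[["cell_id", "fov_id", "x_um", "y_um"]], on="cell_id")
    os_df = df[df["measured_class"].isin(["OS", "both"])].copy()
    if "measured_orientation_group" in os_df.columns:
        os_df["orientation_group"] = os_df["measured_orientation_group"].fillna(
            "overrepresented"
        )
    else:
        os_df["orientation_group"] = "overrepresented"

    hist_rows = []
    for quad in fovs["quadrant"].unique():
        fids = fovs.loc[fovs["quadrant"] == quad, "fov_id"]
        ang = os_df.loc[os_df["fov_id"].isin(fids), "pref_orientation_deg"]
        counts, edges = orientation_histogram(ang, config.histogram_bin_deg)
        for lo, c in zip(edges[:-1], counts):
            hist_rows.append({"quadrant": quad, "bin_lo_deg": lo, "count": int(c)})
    pd.DataFrame(hist_rows).to_csv(out / "orientation_histograms.csv", index=False)

    dev = deviation_vs_distance(os_df, fovs, group="overrepresented")
    dev.to_csv(out / "deviation_vs_distance.csv", index=False)

    ff = flow_field(os_df, grid_um=config.flow_grid_um, min_n=config.flow_min_n)
    ff.to_csv(out / "flow_field.csv", index=False)

    # more- vs less-ventral comparison of per-cell deviations, split at the
    # median FOV y (configurable offset splits are exposed in the library)
    over = os_df[os_df["orientation_group"] == "overrepresented"].copy()
    over["deviation_deg"] = deviation_from_ventral(over["pref_orientation_deg"].to_numpy())
    fov_y = fovs.set_index("fov_id")["center_y_um"]
    y = fov_y.loc[over["fov_id"]].to_numpy()
    split = float(np.median(fovs["center_y_um"]))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(5,)))
    comparison = None
    a, b = over.loc[y < split, "deviation_deg"], over.loc[y >= split, "deviation_deg"]
    if len(a) and len(b):
        comparison = compare_regions(
            a, b, names=("more_ventral", "less_ventral"),
            n_perm=config.region_n_perm, rng=rng,
        )
        (out / "region_comparison.json").write_text(
            json.dumps(dataclasses.asdict(comparison), indent=2, sort_keys=True)
        )
    _manifest_update(
        out,
        "map",
        {
            "orientation_histograms.csv": len(hist_rows),
            "deviation_vs_distance.csv": len(dev),
            "flow_field.csv": len(ff),
        },
        config,
    )
    return dev, ff, comparison


def stage_fit_model(config: PipelineConfig):
    out = _out(config)
    _require(out / "deviation_vs_distance.csv", "map", "fit-model")
    dev = pd.read_csv(out / "deviation_vs_distance.csv")
    measured = {}
    for quad in ("VN", "VT"):
        sub = dev[dev["quadrant"] == quad]
        if len(sub) >= 3:
            measured[quad] = (
                sub["distance_um"].to_numpy(),
                sub["mean_deviation_deg"].to_numpy(),
            )
    if not measured:
        raise MissingStageError(
            "fit-model needs per-FOV curves in the VN/VT quadrants; none found"
        )
    from .concentric import VN_AXIS, VT_AXIS

    axes = {q: a for q, a in (("VN", VN_AXIS), ("VT", VT_AXIS)) if q in measured}
    fitted = fit_anchor_and_aspect(
        measured,
        axes=axes,
        anchor_x_grid=config.grid(config.model_anchor_x),
        anchor_y_grid=config.grid(config.model_anchor_y),
        aspect_grid=config.grid(config.model_aspect),
        y_radii=config.grid(config.model_radii),
        keep_surface=False,
    )
    result = {
        "anchor_x_um": fitted.anchor_xy[0],
        "anchor_y_um": fitted.anchor_xy[1],
        "aspect": fitted.aspect,
        "score_area_deg_um": fitted.score,
        "per_axis_area": {k: v.area_between for k, v in fitted.comparisons.items()},
    }
    (out / "model_fit.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    _manifest_update(out, "fit-model", {"model_fit.json": 1}, config)
    return fitted


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "tune": stage_tune,
    "classify": stage_classify,
    "cluster": stage_cluster,
    "map": stage_map,
    "fit-model": stage_fit_model,
}


def run_pipeline(config: PipelineConfig, stages=STAGES):
    """Run the requested stages in canonical order; returns the manifest."""
    out = _out(config)
    config.to_yaml(out / "config.yaml")
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            STAGE_FUNCS[stage](config)
    return json.loads((out / "manifest.json").read_text())
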