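"""Synthetic retina and calcium-response generator.

Emulates the statistical structure of a population two-photon moving-bar
experiment in the ganglion cell layer: square fields of view (FOVs) placed
in named retinal quadrants around the optic nerve, a realistic density of
segmented somata per FOV, a mixture of orientation-selective (OS),
direction-selective (DS), jointly selective, and untuned cells, three OS
kinetic subtypes (ONs/ONt/OFF) with an inverse prevalence/tuning ordering,
and a preferred-orientation map laid out as tangents of concentric
ellipses anchored in ventronasal retina, with an orthogonal
underrepresented minority group.

Defaults encode the study conditions: 425 x 425 um^2 FOVs with 590 +/- 170
cells, ~30% OS, 12% DS, 0.5% both, subtype mix 70/20/10 (ONs/ONt/OFF) with
tuning concentration OFF > ONt > ONs, 15% underrepresented-group OS cells,
and an ellipse family of aspect 1.09 anchored slightly nasal of the
ventral pole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import wrap_orientation
from .concentric import tangent_axis_through_point
from .responses import StimulusProtocol

__all__ = [
    "RetinaModelConfig",
    "QUADRANT_BANDS",
    "SUBTYPES",
    "generate_retina",
    "kinetic_template",
    "tuning_gain",
    "synthesize_responses",
    "export_toy_movie",
]

#: FOV centers are sampled in bands along the named sampling axes, mirroring
#: the study layout of imaging fields strung along the ventronasal (VN),
#: ventrotemporal (VT), ventral (V) and temporal (T) rays from the optic
#: nerve: (ray angle deg, distance range um, perpendicular offset range um).
QUADRANT_BANDS = {
    "VN": (225.0, (600.0, 2000.0), (0.0, 0.0)),
    "VT": (315.0, (600.0, 2000.0), (0.0, 0.0)),
    "V": (270.0, (700.0, 1900.0), (-300.0, 300.0)),
    "T": (0.0, (700.0, 1900.0), (-300.0, 300.0)),
}

SUBTYPES = ("ONs", "ONt", "OFF")


@dataclass(frozen=True)
class RetinaModelConfig:
    """All knobs of the synthetic retina; defaults are the study conditions."""

    n_fovs: int = 20
    fov_size_um: float = 425.0
    cells_per_fov_mean: float = 590.0
    cells_per_fov_sd: float = 170.0
    frac_os: float = 0.30
    frac_ds: float = 0.12
    frac_both: float = 0.005
    subtype_mix: tuple = (0.70, 0.20, 0.10)  # ONs, ONt, OFF
    #: von Mises concentration of the orientation gain per subtype;
    #: inverse to prevalence (OFF most sharply tuned)
    subtype_tuning_kappa: tuple = (1.0, 2.0, 3.0)
    #: DS tuning is cosine-shaped, g = 1 - m(1-cos d)/2 (pure first harmonic,
    #: so direction tuning adds no orientation-space signal); m is the depth
    ds_modulation: float = 0.8
    underrep_frac: float = 0.15
    map_anchor_xy_um: tuple = (-100.0, -400.0)
    map_aspect_ratio: float = 1.09
    #: concentration of the von Mises angular noise applied in double-angle
    #: space (np.inf = noiseless map)
    angular_noise_kappa: float = 10.0
    quadrants: tuple = ("VN", "VT")
    n_directions: int = 8
    n_reps: int = 5
    frames_per_trial: int = 40
    frame_rate_hz: float = 10.0
    stim_on_window: tuple = (5, 25)
    post_off_window: tuple = (25, 40)
    response_amplitude: float = 1.0
    noise_sd: float = 0.10
    condition: str = "NR"  # {NR, B2KO, DR}; no effect unless condition_effect set
    #: optional hook: callable(cells_df, rng) -> cells_df for power analyses
    condition_effect: object = None
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_os", "frac_ds", "frac_both", "underrep_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_os + self.frac_ds + self.frac_both > 1.0 + 1e-12:
            raise ValueError("selectivity fractions sum above 1")
        if not np.isclose(sum(self.subtype_mix), 1.0):
            raise ValueError("subtype_mix must sum to 1")
        if any(p < 0 for p in self.subtype_mix):
            raise ValueError("subtype_mix proportions must be nonnegative")
        if self.fov_size_um <= 0:
            raise ValueError("fov_size_um must be positive")
        if self.n_directions % 2 != 0:
            raise ValueError("n_directions must be even (opposite-direction pairs)")
        if self.condition not in ("NR", "B2KO", "DR"):
            raise ValueError(f"unknown condition tag {self.condition!r}")
        for q in self.quadrants:
            if q not in QUADRANT_BANDS:
                raise ValueError(f"unknown quadrant {q!r}")

    def protocol(self) -> StimulusProtocol:
        angles = tuple(np.arange(self.n_directions) * 360.0 / self.n_directions)
        return StimulusProtocol(
            direction_angles_deg=angles,
            n_reps=self.n_reps,
            frames_per_trial=self.frames_per_trial,
            frame_rate_hz=self.frame_rate_hz,
            stim_on_window=tuple(self.stim_on_window),
            post_off_window=tuple(self.post_off_window),
        )


def _cell_rng(config, cell_index, stream):
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream, cell_index))
    )


def generate_retina(config: RetinaModelConfig):
    """Sample FOVs and ground-truth cells.

    Returns ``(cells, fovs)`` DataFrames.  OS (and jointly selective) cells
    take their true preferred orientation from the tangent field of the
    configured concentric-ellipse family at the cell's location, rotated
    90 deg for the underrepresented group, with von Mises noise in
    double-angle space.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    half = config.fov_size_um / 2.0

    fov_rows = []
    for i in range(config.n_fovs):
        quad = config.quadrants[i % len(config.quadrants)]
        axis_deg, (d0, d1), (o0, o1) = QUADRANT_BANDS[quad]
        a = np.radians(axis_deg)
        u = np.array([np.cos(a), np.sin(a)])
        perp = np.array([-u[1], u[0]])
        cx, cy = rng.uniform(d0, d1) * u + rng.uniform(o0, o1) * perp
        fov_rows.append(
            {
                "fov_id": i,
                "center_x_um": cx,
                "center_y_um": cy,
                "quadrant": quad,
                "distance_um": float(np.hypot(cx, cy)),
            }
        )
    fovs = pd.DataFrame(fov_rows)

    kappa_by_subtype = dict(zip(SUBTYPES, config.subtype_tuning_kappa))
    p_class = [
        config.frac_os,
        config.frac_ds,
        config.frac_both,
        1.0 - config.frac_os - config.frac_ds - config.frac_both,
    ]
    classes = np.array(["OS", "DS", "both", "none"])

    rows = []
    cell_id = 0
    for fov in fov_rows:
        n = max(1, int(round(rng.normal(config.cells_per_fov_mean, config.cells_per_fov_sd))))
        xs = rng.uniform(fov["center_x_um"] - half, fov["center_x_um"] + half, size=n)
        ys = rng.uniform(fov["center_y_um"] - half, fov["center_y_um"] + half, size=n)
        cls = classes[rng.choice(4, size=n, p=p_class)]
        subtype = np.array(
            [SUBTYPES[j] for j in rng.choice(3, size=n, p=list(config.subtype_mix))]
        )
        base_axis = tangent_axis_through_point(
            config.map_anchor_xy_um, config.map_aspect_ratio, np.column_stack([xs, ys])
        )
        underrep = rng.random(n) < config.underrep_frac
        if np.isfinite(config.angular_noise_kappa):
            noise = np.degrees(rng.vonmises(0.0, config.angular_noise_kappa, size=n)) / 2.0
        else:
            noise = np.zeros(n)
        ori = wrap_orientation(base_axis + np.where(underrep, 90.0, 0.0) + noise)
        direction = rng.uniform(0.0, 360.0, size=n)
        for j in range(n):
            is_os = cls[j] in ("OS", "both")
            is_ds = cls[j] in ("DS", "both")
            rows.append(
                {
                    "cell_id": cell_id,
                    "fov_id": fov["fov_id"],
                    "x_um": xs[j],
                    "y_um": ys[j],
                    "selectivity_class": cls[j],
                    "subtype": subtype[j] if is_os else "n/a",
                    "orientation_group": (
                        ("underrepresented" if underrep[j] else "overrepresented")
                        if is_os
                        else "n/a"
                    ),
                    "true_pref_orientation_deg": float(ori[j]) if is_os else np.nan,
                    "true_pref_direction_deg": float(direction[j]) if is_ds else np.nan,
                    "true_tuning_strength": (
                        kappa_by_subtype[subtype[j]]
                        if is_os
                        else (config.ds_modulation if is_ds else 0.0)
                    ),
                    "ds_modulation": config.ds_modulation if is_ds else np.nan,
                    # every cell keeps a kinetic subtype so untuned cells
                    # still have realistic trace shapes
                    "kinetic_template": subtype[j],
                }
            )
            cell_id += 1
    cells = pd.DataFrame(rows)
    if config.condition_effect is not None:
        cells = config.condition_effect(cells, rng)
    return cells, fovs


def kinetic_template(subtype: str, proto: StimulusProtocol) -> np.ndarray:
    """Unit-peak ΔF/F trial template for one kinetic subtype.

    Piecewise double-exponentials (time constants in seconds):
    ONs — fast rise at light onset (0.15), slow sag during the bar (8.0),
    pronounced decay after offset (0.6).  ONt — fast rise at onset (0.10)
    with a 0.35 decay.  OFF — silent during the bar, transient after offset
    (rise 0.10, decay 0.35).
    """
    t = np.arange(proto.frames_per_trial) / proto.frame_rate_hz
    t_on = proto.stim_on_window[0] / proto.frame_rate_hz
    t_off = proto.stim_on_window[1] / proto.frame_rate_hz
    y = np.zeros_like(t)
    if subtype == "ONs":
        on = t >= t_on
        y[on] = (1.0 - np.exp(-(t[on] - t_on) / 0.15)) * np.exp(-(t[on] - t_on) / 8.0)
        post = t >= t_off
        y_at_off = np.interp(t_off, t, y)
        y[post] = y_at_off * np.exp(-(t[post] - t_off) / 0.6)
    elif subtype == "ONt":
        on = t >= t_on
        y[on] = (1.0 - np.exp(-(t[on] - t_on) / 0.10)) * np.exp(-(t[on] - t_on) / 0.35)
    elif subtype == "OFF":
        post = t >= t_off
        y[post] = (1.0 - np.exp(-(t[post] - t_off) / 0.10)) * np.exp(
            -(t[post] - t_off) / 0.35
        )
    else:
        raise ValueError(f"unknown kinetic subtype {subtype!r}")
    return y / y.max()


def tuning_gain(cell_row, angles_deg) -> np.ndarray:
    """Per-direction response gain in (0, 1], maximal at the preferred stimulus.

    OS cells: von Mises in double-angle space around the preferred axis.
    DS cells: cosine modulation around the preferred direction (no
    double-angle component, so DS tuning alone carries no orientation
    signal).  Jointly selective cells: product of the two.  Untuned: flat 1.
    """
    angles = np.asarray(angles_deg, dtype=float)
    gain = np.ones_like(angles)
    cls = cell_row["selectivity_class"]
    if cls in ("OS", "both"):
        kappa = float(cell_row["true_tuning_strength"])
        d = np.radians(2.0 * (angles - cell_row["true_pref_orientation_deg"]))
        gain = gain * np.exp(kappa * (np.cos(d) - 1.0))
    if cls in ("DS", "both"):
        m = float(cell_row["ds_modulation"])
        d = np.radians(angles - cell_row["true_pref_direction_deg"])
        gain = gain * (1.0 - m * (1.0 - np.cos(d)) / 2.0)
    return gain


def synthesize_responses(cells: pd.DataFrame, config: RetinaModelConfig) -> np.ndarray:
    """ΔF/F stacks for every cell; shape (n_cells, k, T, R).

    Each trial trace is the cell's kinetic template scaled by its tuning
    gain at the trial's direction, plus i.i.d. Gaussian noise of sd
    ``config.noise_sd``.  Per-cell RNG substreams make the output
    independent of evaluation order.
    """
    proto = config.protocol()
    angles = np.asarray(proto.direction_angles_deg)
    templates = {s: kinetic_template(s, proto) for s in SUBTYPES}
    out = np.empty(
        (len(cells), proto.n_directions, proto.frames_per_trial, proto.n_reps)
    )
    for i, (_, row) in enumerate(cells.iterrows()):
        gain = tuning_gain(row, angles)
        base = np.broadcast_to(
            config.response_amplitude
            * gain[:, None, None]
            * templates[row["kinetic_template"]][None, :, None],
            out.shape[1:],
        ).copy()
        if config.noise_sd > 0:
            rng = _cell_rng(config, int(row["cell_id"]), stream=1)
            base = base + rng.normal(0.0, config.noise_sd, size=base.shape)
        out[i] = base
    return out


def export_toy_movie(path, config: RetinaModelConfig | None = None, f0=100.0, n_frames=30):
    """Write a tiny synthetic raw-fluorescence TIFF movie (stimulus frames
    brighter in a central blob) for exercising ΔF/F extraction on imagery.

    Returns the boolean stimulus-frame mask.
    """
    import tifffile

    if config is None:
        config = RetinaModelConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    h = w = 32
    yy, xx = np.mgrid[0:h, 0:w]
    blob = np.exp(-(((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / (2 * 5.0**2)))
    stim = np.zeros(n_frames, dtype=bool)
    stim[n_frames // 3 : 2 * n_frames // 3] = True
    movie = f0 * (1.0 + 0.8 * blob[None] * stim[:, None, None])
    movie = movie + rng.normal(0.0, 1.0, movie.shape)
    tifffile.imwrite(path, movie.astype(np.float32))
    return stim
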