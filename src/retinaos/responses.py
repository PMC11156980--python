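"""Per-cell tuning analysis of moving-bar calcium responses.

A cell's recording is a stack of ΔF/F response matrices, one per motion
direction, each of shape (T frames, R repetitions).  This module computes
the ΔF/F normalization, per-direction peak responses, the variance-ratio
quality index, and the four selectivity statistics:

* ``L_dir = |Σ_k R(θ_k) e^{iθ_k}| / Σ_k R(θ_k)`` — normalized resultant in
  direction space; its phase is the preferred direction.
* ``L_ori = |Σ_k R(θ_k) e^{2iθ_k}| / Σ_k R(θ_k)`` — the same in double-angle
  (orientation) space; half its phase is the preferred orientation.
* DSI — (pref − null)/(pref + null) on the sampled direction nearest the
  vector sum and its 180 deg opposite.
* OSI — (pref − orthogonal)/(pref + orthogonal) on the four
  opposite-direction-averaged orientation responses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .angles import wrap_direction, wrap_orientation

__all__ = [
    "StimulusProtocol",
    "TuningSummary",
    "compute_dfof",
    "trial_peaks",
    "peak_responses",
    "quality_index",
    "cell_quality_index",
    "direction_selectivity",
    "orientation_selectivity",
    "summarize_cell",
    "NoBaselineError",
    "DegenerateBaselineError",
    "UndefinedTuningError",
]


class NoBaselineError(ValueError):
    """Every frame is marked as stimulus: no baseline F can be isolated."""


class DegenerateBaselineError(ValueError):
    """Baseline fluorescence F0 is zero; ΔF/F is undefined."""


class UndefinedTuningError(ValueError):
    """All peak responses are zero; preferred angles are undefined."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Moving-bar protocol: k directions x R repetitions x T frames.

    Windows are half-open frame intervals, 0-based.  ``stim_on_window``
    covers the bar presentation; ``post_off_window`` the frames after bar
    offset in which OFF responses occur.  Peak extraction uses the union of
    the two by default (the response window).
    """

    direction_angles_deg: tuple = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    n_reps: int = 5
    frames_per_trial: int = 40
    frame_rate_hz: float = 10.0
    stim_on_window: tuple = (5, 25)
    post_off_window: tuple = (25, 40)

    def __post_init__(self):
        angles = wrap_direction(self.direction_angles_deg)
        if len(set(np.round(angles, 9))) != len(angles):
            raise ValueError("stimulus direction angles must be distinct")
        for a in angles:
            opp = (a + 180.0) % 360.0
            if not np.any(np.isclose(angles, opp)):
                raise ValueError(
                    f"direction {a} deg has no 180-deg opposite; orientation "
                    "averaging requires opposite-direction pairs"
                )
        for name in ("stim_on_window", "post_off_window"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= self.frames_per_trial):
                raise ValueError(f"{name} {lo, hi} outside [0, {self.frames_per_trial})")

    @property
    def n_directions(self) -> int:
        return len(self.direction_angles_deg)

    @property
    def response_window(self) -> tuple:
        return (self.stim_on_window[0], self.post_off_window[1])

    @property
    def orientation_angles_deg(self) -> np.ndarray:
        """Unique stimulus axes in [0, 180), sorted."""
        return np.unique(wrap_orientation(np.asarray(self.direction_angles_deg)))


@dataclass
class TuningSummary:
    """All per-cell tuning quantities derived from one recording."""

    peaks: np.ndarray                      # ΔF/F peak per direction, order of protocol angles
    qi: float
    qi_degenerate: bool
    l_dir: float
    dsi: float
    pref_direction_deg: float              # phase of the direction-space vector sum
    pref_direction_sampled_deg: float      # sampled direction nearest the vector sum
    l_ori: float
    osi: float
    pref_orientation_deg: float            # half the double-angle phase, in [0, 180)
    pref_orientation_sampled_deg: float    # axis with the largest averaged response

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        peaks = d.pop("peaks")
        d.update({f"peak_{i}": float(p) for i, p in enumerate(peaks)})
        return d


def compute_dfof(raw, stimulus_frames):
    """ΔF/F normalization: (F − F0)/F0 with F0 the mean of non-stimulus frames.

    Parameters
    ----------
    raw : array, time on axis 0 (a trace or a movie).
    stimulus_frames : boolean mask over axis 0 (True = stimulus shown) or an
        integer index array of stimulus frames.
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.zeros(raw.shape[0], dtype=bool)
    stim = np.asarray(stimulus_frames)
    if stim.dtype == bool:
        if stim.shape[0] != raw.shape[0]:
            raise ValueError("stimulus mask length does not match trace length")
        mask[:] = stim
    else:
        mask[stim] = True
    if mask.all():
        raise NoBaselineError("all frames are stimulus frames; no baseline F")
    f0 = raw[~mask].mean(axis=0)
    if np.any(f0 == 0):
        raise DegenerateBaselineError("baseline F0 is zero")
    return (raw - f0) / f0


def _check_rm(rm):
    rm = np.asarray(rm, dtype=float)
    if rm.ndim != 3:
        raise ValueError("response stack must have shape (n_directions, T, R)")
    if not np.all(np.isfinite(rm)):
        raise ValueError("response matrix contains non-finite values")
    return rm


def trial_peaks(rm, proto: StimulusProtocol, window=None):
    """Per-trial maximum ΔF/F inside the response window; shape (k, R)."""
    rm = _check_rm(rm)
    lo, hi = window if window is not None else proto.response_window
    if hi <= lo:
        raise ValueError("empty response window")
    return rm[:, lo:hi, :].max(axis=1)


def peak_responses(rm, proto: StimulusProtocol, window=None):
    """Average peak ΔF/F per direction: mean over repetitions of each
    repetition's maximum inside the response window."""
    return trial_peaks(rm, proto, window).mean(axis=1)


def quality_index(C):
    """Variance-ratio response reliability of one T x R response matrix.

    QI = Var_t[ <C>_r ] / < Var_t[C] >_r : the temporal variance of the
    repetition-averaged trace over the repetition-averaged temporal
    variance.  Equals 1 when all repetitions are identical.  When every
    repetition is constant in time the ratio is 0/0; by convention we
    return 0 with a degeneracy flag so batch pipelines proceed.

    Returns ``(qi, degenerate)``.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("response matrix must be 2-D (T, R)")
    num = C.mean(axis=1).var()
    den = C.var(axis=0).mean()
    if den == 0.0:
        return 0.0, True
    return float(num / den), False


def cell_quality_index(rm):
    """Cell-level QI: the k per-direction matrices concatenated along time
    into one (k*T, R) matrix, so one repetition is a full direction sweep."""
    rm = _check_rm(rm)
    k, T, R = rm.shape
    return quality_index(rm.transpose(0, 1, 2).reshape(k * T, R))


def _clean_peaks(peaks, angles):
    peaks = np.asarray(peaks, dtype=float)
    angles = wrap_direction(angles)
    if peaks.shape != angles.shape:
        raise ValueError("peaks and angles must align")
    # ΔF/F noise can make individual peaks slightly negative; the resultant
    # statistics assume nonnegative weights
    peaks = np.clip(peaks, 0.0, None)
    if peaks.sum() == 0.0:
        raise UndefinedTuningError("all peak responses are zero")
    return peaks, angles


def direction_selectivity(peaks, angles_deg):
    """(l_dir, dsi, pref_direction_deg, pref_direction_sampled_deg)."""
    peaks, angles = _clean_peaks(peaks, angles_deg)
    z = np.sum(peaks * np.exp(1j * np.radians(angles)))
    l_dir = float(np.abs(z) / peaks.sum())
    pref = wrap_direction(np.degrees(np.angle(z)))
    # sampled pref: protocol direction closest to the vector sum (circular)
    d = np.abs((angles - pref + 180.0) % 360.0 - 180.0)
    i_pref = int(np.argmin(d))
    null_angle = (angles[i_pref] + 180.0) % 360.0
    i_null = int(np.argmin(np.abs((angles - null_angle + 180.0) % 360.0 - 180.0)))
    rp, rn = peaks[i_pref], peaks[i_null]
    dsi = 0.0 if rp + rn == 0 else float((rp - rn) / (rp + rn))
    return l_dir, dsi, float(pref), float(angles[i_pref])


def orientation_selectivity(peaks, angles_deg):
    """(l_ori, osi, pref_orientation_deg, pref_orientation_sampled_deg).

    OSI averages the peak responses of opposite direction pairs into
    orientation responses first; pref is the axis with the largest averaged
    response (which can differ from the vector-sum phase; both are kept).
    """
    peaks, angles = _clean_peaks(peaks, angles_deg)
    z = np.sum(peaks * np.exp(2j * np.radians(angles)))
    l_ori = float(np.abs(z) / peaks.sum())
    pref_ori = wrap_orientation(np.degrees(np.angle(z)) / 2.0)

    axes = np.unique(np.round(wrap_orientation(angles), 9))
    ori_resp = np.array(
        [peaks[np.isclose(wrap_orientation(angles), ax)].mean() for ax in axes]
    )
    i_pref = int(np.argmax(ori_resp))
    orth_axis = (axes[i_pref] + 90.0) % 180.0
    match = np.isclose(axes, orth_axis)
    if not match.any():
        raise ValueError(
            f"protocol has no axis orthogonal to {axes[i_pref]} deg; OSI undefined"
        )
    i_orth = int(np.argmax(match))
    rp, ro = ori_resp[i_pref], ori_resp[i_orth]
    osi = 0.0 if rp + ro == 0 else float((rp - ro) / (rp + ro))
    return l_ori, osi, float(pref_ori), float(axes[i_pref])


def summarize_cell(rm, proto: StimulusProtocol) -> TuningSummary:
    """Full tuning summary for one cell's (k, T, R) ΔF/F stack."""
    peaks = peak_responses(rm, proto)
    qi, degen = cell_quality_index(rm)
    angles = np.asarray(proto.direction_angles_deg, dtype=float)
    l_dir, dsi, pref_dir, pref_dir_s = direction_selectivity(peaks, angles)
    l_ori, osi, pref_ori, pref_ori_s = orientation_selectivity(peaks, angles)
    return TuningSummary(
        peaks=peaks,
        qi=qi,
        qi_degenerate=degen,
        l_dir=l_dir,
        dsi=dsi,
        pref_direction_deg=pref_dir,
        pref_direction_sampled_deg=pref_dir_s,
        l_ori=l_ori,
        osi=osi,
        pref_orientation_deg=pref_ori,
        pref_orientation_sampled_deg=pref_ori_s,
    )
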