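"""Unit and property tests for ΔF/F, peaks, QI, and selectivity statistics."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinaos import (
    StimulusProtocol,
    compute_dfof,
    direction_selectivity,
    orientation_selectivity,
    peak_responses,
    quality_index,
    summarize_cell,
)
from retinaos.responses import (
    DegenerateBaselineError,
    NoBaselineError,
    UndefinedTuningError,
    cell_quality_index,
    trial_peaks,
)

ANGLES8 = np.arange(8) * 45.0


def brute_l(peaks, angles_deg, double):
    """Independent oracle: direct complex summation with cmath."""
    num = sum(
        p * cmath.exp(1j * ((2 if double else 1) * cmath.pi / 180 * a))
        for p, a in zip(peaks, angles_deg)
    )
    return abs(num) / sum(peaks)


class TestDfof:
    def test_constant_trace_is_zero(self):
        out = compute_dfof(np.full(10, 3.0), np.zeros(10, dtype=bool))
        assert np.allclose(out, 0.0)

    def test_simple_stimulus_step(self):
        raw = np.ones(10)
        stim = np.zeros(10, dtype=bool)
        stim[4:7] = True
        raw[stim] = 2.0
        out = compute_dfof(raw, stim)
        assert np.allclose(out[stim], 1.0)
        assert np.allclose(out[~stim], 0.0)

    def test_mixed_baseline_arithmetic(self):
        # baseline frames {1, 3} -> F0 = 2; stimulus frame at 5 -> (5-2)/2
        raw = np.array([1.0, 3.0, 5.0])
        stim = np.array([False, False, True])
        out = compute_dfof(raw, stim)
        assert out[2] == pytest.approx(1.5)

    def test_errors(self):
        with pytest.raises(NoBaselineError):
            compute_dfof(np.ones(5), np.ones(5, dtype=bool))
        with pytest.raises(DegenerateBaselineError):
            compute_dfof(np.zeros(5), np.zeros(5, dtype=bool))

    def test_movie_axis(self):
        movie = np.ones((6, 2, 2))
        stim = np.array([False, False, True, True, False, False])
        movie[stim] = 3.0
        out = compute_dfof(movie, stim)
        assert out.shape == movie.shape
        assert np.allclose(out[stim], 2.0)


class TestPeaks:
    def test_identical_trials(self, proto):
        rm = np.zeros((8, 40, 5))
        rm[:, 10, :] = 2.0
        assert np.allclose(peak_responses(rm, proto), 2.0)

    def test_mean_of_per_trial_maxima(self, proto):
        rm = np.zeros((8, 40, 2))
        rm[0, 12, 0] = 1.0
        rm[0, 15, 1] = 3.0
        assert peak_responses(rm, proto)[0] == pytest.approx(2.0)

    def test_window_excludes_pre_stimulus(self, proto):
        rm = np.zeros((8, 40, 1))
        rm[:, 0, :] = 5.0  # before the response window
        rm[:, 10, :] = 1.0
        assert np.allclose(peak_responses(rm, proto), 1.0)

    def test_empty_window_errors(self, proto):
        with pytest.raises(ValueError):
            trial_peaks(np.zeros((8, 40, 2)), proto, window=(10, 10))


class TestQualityIndex:
    def test_identical_repeats_give_one(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(size=100)
        C = np.tile(trace[:, None], (1, 5))
        qi, degen = quality_index(C)
        assert qi == pytest.approx(1.0)
        assert not degen

    def test_single_repetition_gives_one(self):
        qi, _ = quality_index(np.arange(10.0)[:, None])
        assert qi == pytest.approx(1.0)

    def test_constant_matrix_degenerate(self):
        qi, degen = quality_index(np.full((10, 4), 2.0))
        assert qi == 0.0 and degen

    def test_iid_noise_approaches_one_over_r(self):
        # Var_t[mean of R iid traces] = sigma^2/R while <Var_t> = sigma^2
        rng = np.random.default_rng(1)
        R = 5
        qis = [quality_index(rng.normal(size=(2000, R)))[0] for _ in range(20)]
        assert np.mean(qis) == pytest.approx(1.0 / R, abs=0.02)

    def test_cell_level_concatenates_directions(self, proto):
        rng = np.random.default_rng(2)
        rm = np.tile(rng.normal(size=(8, 40, 1)), (1, 1, 5))
        qi, _ = cell_quality_index(rm)
        assert qi == pytest.approx(1.0)


class TestDirectionSelectivity:
    def test_single_direction_fully_selective(self):
        l_dir, dsi, pref, pref_s = direction_selectivity([1, 0, 0, 0, 0, 0, 0, 0], ANGLES8)
        assert l_dir == pytest.approx(1.0)
        assert dsi == pytest.approx(1.0)
        assert pref == pytest.approx(0.0)
        assert pref_s == 0.0

    def test_flat_peaks_unselective(self):
        l_dir, dsi, _, _ = direction_selectivity(np.ones(8), ANGLES8)
        assert l_dir == pytest.approx(0.0, abs=1e-12)
        assert dsi == pytest.approx(0.0)

    def test_one_above_flat_is_one_ninth(self):
        # unit vectors cancel; the extra response of 1 at 0 deg remains
        l_dir, _, pref, _ = direction_selectivity([2, 1, 1, 1, 1, 1, 1, 1], ANGLES8)
        assert l_dir == pytest.approx(1.0 / 9.0, abs=1e-12)
        assert pref == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(UndefinedTuningError):
            direction_selectivity(np.zeros(8), ANGLES8)


class TestOrientationSelectivity:
    def test_flat_peaks_unselective(self):
        l_ori, osi, _, _ = orientation_selectivity(np.ones(8), ANGLES8)
        assert l_ori == pytest.approx(0.0, abs=1e-12)
        assert osi == pytest.approx(0.0)

    def test_opposite_pair_is_pure_orientation(self):
        # responses at 0 and 180 cancel in direction space, add in
        # double-angle space
        peaks = [1, 0, 0, 0, 1, 0, 0, 0]
        l_ori, osi, pref, _ = orientation_selectivity(peaks, ANGLES8)
        l_dir, _, _, _ = direction_selectivity(peaks, ANGLES8)
        assert l_ori == pytest.approx(1.0)
        assert l_dir == pytest.approx(0.0, abs=1e-12)
        assert pref == pytest.approx(0.0, abs=1e-9)
        assert osi == pytest.approx(1.0)

    def test_osi_from_orientation_averages(self):
        # averaged orientation responses: 3 (axis 0), 2, 1 (axis 90), 2
        peaks = [3, 2, 1, 2, 3, 2, 1, 2]
        _, osi, _, pref_s = orientation_selectivity(peaks, ANGLES8)
        assert osi == pytest.approx(0.5)
        assert pref_s == 0.0

    def test_single_direction_degeneracy(self):
        # a cell responding to exactly one direction maxes out both indices,
        # which is why significance is assessed jointly
        peaks = [1, 0, 0, 0, 0, 0, 0, 0]
        l_ori, _, _, _ = orientation_selectivity(peaks, ANGLES8)
        l_dir, _, _, _ = direction_selectivity(peaks, ANGLES8)
        assert l_ori == pytest.approx(1.0)
        assert l_dir == pytest.approx(1.0)


@settings(max_examples=100, derandomize=True)
@given(
    peaks=st.lists(st.floats(0.01, 10.0), min_size=8, max_size=8),
    delta=st.floats(-360.0, 360.0),
)
def test_rotation_equivariance(peaks, delta):
    """Rotating all stimulus angles rotates the preferred angles and leaves
    the resultant lengths unchanged."""
    l_dir0, _, pref0, _ = direction_selectivity(peaks, ANGLES8)
    l_ori0, _, po0, _ = orientation_selectivity(peaks, ANGLES8)
    rotated = (ANGLES8 + delta) % 360.0
    l_dir1, _, pref1, _ = direction_selectivity(peaks, rotated)
    l_ori1, _, po1, _ = orientation_selectivity(peaks, rotated)
    assert l_dir1 == pytest.approx(l_dir0, abs=1e-9)
    assert l_ori1 == pytest.approx(l_ori0, abs=1e-9)
    if l_dir0 > 1e-6:
        assert (pref1 - pref0 - delta) % 360.0 == pytest.approx(0.0, abs=1e-6) or (
            pref1 - pref0 - delta
        ) % 360.0 == pytest.approx(360.0, abs=1e-6)
    if l_ori0 > 1e-6:
        d = (po1 - po0 - delta) % 180.0
        assert min(d, 180.0 - d) == pytest.approx(0.0, abs=1e-6)


@settings(max_examples=200, derandomize=True)
@given(peaks=st.lists(st.floats(0.0, 10.0), min_size=8, max_size=8))
def test_oracle_equivalence_and_bounds(peaks):
    """l_dir/l_ori equal brute-force complex sums and stay in [0, 1]."""
    if sum(peaks) == 0:
        return
    l_dir, dsi, _, _ = direction_selectivity(peaks, ANGLES8)
    l_ori, osi, _, _ = orientation_selectivity(peaks, ANGLES8)
    assert l_dir == pytest.approx(brute_l(peaks, ANGLES8, double=False), abs=1e-12)
    assert l_ori == pytest.approx(brute_l(peaks, ANGLES8, double=True), abs=1e-12)
    for v in (l_dir, l_ori, osi):
        assert -1e-12 <= v <= 1.0 + 1e-12
    # DSI can go negative for adversarial peak patterns (the sampled
    # direction nearest the vector sum need not be the largest response)
    assert -1.0 - 1e-12 <= dsi <= 1.0 + 1e-12


def test_summarize_cell_fields(small_retina):
    cfg, cells, _, responses = small_retina
    ts = summarize_cell(responses[0], cfg.protocol())
    assert 0.0 <= ts.l_dir <= 1.0 and 0.0 <= ts.l_ori <= 1.0
    assert 0.0 <= ts.pref_orientation_deg < 180.0
    assert 0.0 <= ts.pref_direction_deg < 360.0
    d = ts.as_dict()
    assert "peak_0" in d and "peaks" not in d


def test_protocol_requires_opposite_pairs():
    with pytest.raises(ValueError):
        StimulusProtocol(direction_angles_deg=(0.0, 45.0, 90.0))
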