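"""Switching prediction geometry and rate-model pulse experiments."""

import numpy as np
import pytest

from effconn.phase import LockingFunctional, ResponseCurve, find_lockings
from effconn.switching import (predict_intervals, TwoAreaRateModel, apply_pulse,
                               locking_labels, epoch_mask, _mask_to_intervals)
from effconn.rate import RateModelParams


def _bistable_g():
    """Two stable lockings at 0.33 and 0.67 of the circle (pitchfork-like)."""
    x = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    g = np.sin(x) * (np.cos(x) + 0.5)      # zeros at 0, pi and cos = -1/2
    return LockingFunctional(dphi=x, g=-g)


def _response(amp):
    phases = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    shift = amp * np.clip(np.sin(phases), -0.4, None)   # advance-dominated
    return ResponseCurve(phases=phases, shift=shift, lo=shift, hi=shift, strength=1.0)


class TestPredictIntervals:
    def test_zero_pulse_empty(self):
        pred = predict_intervals(_bistable_g(), _response(0.0), 0.0, role="laggard")
        assert pred.intervals == []

    def test_small_kick_cannot_leave_basin(self):
        g = _bistable_g()
        locks = [L for L in find_lockings(g) if L.stable]
        # distance from either stable zero to its basin edge exceeds 0.3 rad here
        pred = predict_intervals(g, _response(0.1), 1.0, role="laggard")
        assert pred.intervals == []

    def test_large_kick_gives_intervals(self):
        pred = predict_intervals(_bistable_g(), _response(3.0), 1.0, role="laggard")
        assert pred.intervals
        total = sum((b - a) % (2 * np.pi) for a, b in pred.intervals)
        assert 0 < total < 2 * np.pi

    def test_reversal_symmetry(self):
        """Leader interval at locking dphi* equals laggard interval at 2pi - dphi*."""
        g = _bistable_g()
        stable = sorted(L.dphi for L in find_lockings(g) if L.stable)
        resp = _response(3.0)
        a = predict_intervals(g, resp, 1.0, role="leader", current_locking=stable[0])
        b = predict_intervals(g, resp, 1.0, role="laggard", current_locking=2 * np.pi - stable[0])
        assert a.success_mask is not None
        np.testing.assert_array_equal(a.success_mask, b.success_mask)

    def test_monostable_warns_and_returns_empty(self):
        x = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        g = LockingFunctional(dphi=x, g=-np.sin(x))
        with pytest.warns(UserWarning):
            pred = predict_intervals(g, _response(3.0), 1.0, role="laggard")
        assert pred.intervals == []


def test_mask_to_intervals_handles_wraparound():
    grid = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    mask = np.array([True, True, False, False, False, False, False, True])
    ivs = _mask_to_intervals(grid, mask)
    assert len(ivs) == 1
    a, b = ivs[0]
    assert a == pytest.approx(grid[7]) and b == pytest.approx(grid[1])


@pytest.fixture(scope="module")
def model():
    p = RateModelParams(n_areas=2, i0=1.0, k_local=20.0, k_cross=0.1,
                        d_local=1.0, d_cross=0.5, dt=0.01, duration=600.0)
    return TwoAreaRateModel(p)


class TestRatePulse:

    def test_null_phase_retains_motif(self, model):
        # phase 0 sits where the induced shift is small: no switch
        before, after, _ = apply_pulse(model, 0, 0.0, 0.08)
        assert before == after != "none"

    def test_effective_phase_switches_and_settles_fast(self, model):
        # a pulse in the effective window reverses directionality
        before, after, latency = apply_pulse(model, 0, 0.75 * 2 * np.pi, 0.08)
        assert before != after and "none" not in (before, after)
        assert latency <= 10

    def test_deterministic_success_is_binary(self, model):
        from effconn.switching import success_histogram
        grid = np.array([0.0, 0.75 * 2 * np.pi])
        exp = success_histogram(model, 0, 0.08, phase_grid=grid, trials=2, seed=0)
        assert set(exp.success_frequency.tolist()) <= {0.0, 1.0}


class TestEpochLabels:
    def test_labels_track_imposed_lag(self):
        T = 10.0
        t = np.arange(0, 600, 0.05)
        x0 = np.sin(2 * np.pi * t / T)
        x1 = np.sin(2 * np.pi * (t - 2.0) / T)     # area 0 leads
        starts, labels = locking_labels(t, x0, x1)
        nz = labels[labels != 0]
        assert nz.size > 0 and (nz == 1).mean() > 0.9

    def test_mask_drops_switch_transients(self):
        T = 10.0
        t = np.arange(0, 1200, 0.05)
        lagging = np.where(t < 600, 2.0, -2.0)     # leadership flips mid-run
        x0 = np.sin(2 * np.pi * t / T)
        x1 = np.sin(2 * np.pi * (t - lagging) / T)
        starts, labels = locking_labels(t, x0, x1)
        mask = epoch_mask(t, starts, labels, drop_after_change=5)
        # dominant half kept, other half dropped
        assert 0.3 < mask.mean() < 0.65
        # nothing kept right at the flip
        flip = np.abs(t - 600) < 2 * T
        assert not mask[flip].any()
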