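"""Phase reduction, response measurement and locking-state analysis."""

import numpy as np
import pytest
from dataclasses import replace

from effconn.rate import RateModelParams, simulate_rate, detect_cycles
from effconn.phase import (empiric_phase, measured_lag, measure_response,
                           adjoint_prc, limit_cycle_waveform, locking_functional,
                           find_lockings, LockingFunctional, RatePulseModel)


class TestEmpiricPhase:
    def test_periodic_series(self):
        T = 10.0
        t = np.arange(0, 200, 0.01)
        cyc = detect_cycles(t, np.sin(2 * np.pi * t / T))
        ph = empiric_phase(t, cyc)
        probe = np.arange(30.0, 150.0, 0.37)
        expected = np.mod(2 * np.pi * probe / T, 2 * np.pi)
        got = ph(probe)
        err = np.abs(np.angle(np.exp(1j * (got - expected))))
        assert err.max() < 0.02

    def test_alternating_cycle_lengths(self):
        # cycle starts at 0, 10, 30, 40, 60 ... alternating T and 2T
        starts = np.cumsum([0] + [10, 20] * 6).astype(float)
        from effconn.rate import CyclePeaks
        cyc = CyclePeaks(area=0, peak_times=starts[:-1] + 1, peak_amplitudes=np.ones(starts.size - 1),
                         start_times=starts, mean_period=15.0)
        ph = empiric_phase(np.arange(0, 150.0, 0.1), cyc)
        # phase zero at every start, and mid-cycle phase is pi regardless of length
        assert np.allclose(ph(starts[:-1]), 0.0, atol=1e-9)
        mids = (starts[:-1] + starts[1:]) / 2
        assert np.allclose(ph(mids), np.pi, atol=1e-9)

    def test_chaotic_series_gains_2pi_per_cycle(self):
        p = RateModelParams(n_areas=2, i0=1.0, k_local=20.0, k_cross=8.0,
                            d_local=1.0, d_cross=0.5, dt=0.01, duration=800.0)
        traj = simulate_rate(p, init_history=np.array([0.05, 0.08]))
        sel = traj.times > 400
        cyc = detect_cycles(traj.times[sel], traj.rates[sel, 0])
        ph = empiric_phase(traj.times[sel], cyc)
        unw = ph.unwrapped(cyc.start_times)
        np.testing.assert_allclose(np.diff(unw), 2 * np.pi, atol=1e-6)

    def test_rejects_flat_input(self):
        t = np.arange(0, 10, 0.01)
        cyc = detect_cycles(t, np.ones_like(t))
        with pytest.raises(ValueError):
            empiric_phase(t, cyc)


def test_measured_lag_sign_and_value():
    T, delta = 10.0, 2.0
    t = np.arange(0, 400, 0.05)
    x = np.sin(2 * np.pi * t / T)
    y = np.sin(2 * np.pi * (t - delta) / T)
    assert measured_lag(x, y, 0.05, T) == pytest.approx(delta, abs=0.05)
    assert measured_lag(y, x, 0.05, T) == pytest.approx(-delta, abs=0.05)


class TestResponse:
    def test_zero_pulse_zero_shift(self, osc_params):
        model = RatePulseModel(osc_params, init_history=0.1, settle_time=80.0)
        resp = measure_response(model, 0, 0.0, phase_grid=6, trials=1, seed=0)
        assert np.nanmax(np.abs(resp.shift)) < 0.02

    def test_small_pulse_matches_adjoint_prc(self, osc_params):
        """Finite-pulse measurement vs the adjoint-equation infinitesimal PRC."""
        prc = adjoint_prc(osc_params)
        model = RatePulseModel(osc_params, init_history=0.1, settle_time=100.0)
        A = 0.005
        meas = measure_response(model, 0, A, phase_grid=16, trials=1, seed=0)
        pred = A * prc.interp(meas.phases)
        assert np.max(np.abs(meas.shift - pred)) <= 0.10 * np.ptp(pred)

    def test_positive_lobe_dominates_for_moderate_pulses(self, osc_params):
        # advances outweigh delays for moderate finite pulses (at large
        # strengths the advance saturates while the delay lobe keeps growing)
        model = RatePulseModel(osc_params, init_history=0.1, settle_time=100.0)
        resp = measure_response(model, 0, 0.02, phase_grid=24, trials=1, seed=0)
        pos = np.trapezoid(np.clip(resp.shift, 0, None), resp.phases)
        neg = np.trapezoid(np.clip(-resp.shift, 0, None), resp.phases)
        assert pos > neg


class TestLockings:
    def test_minus_sine_stable_at_zero(self):
        x = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        locks = find_lockings(LockingFunctional(dphi=x, g=-np.sin(x)))
        stable = [L for L in locks if L.stable]
        unstable = [L for L in locks if not L.stable]
        assert len(stable) == 1 and stable[0].dphi == pytest.approx(0.0, abs=0.02)
        assert len(unstable) == 1 and unstable[0].dphi == pytest.approx(np.pi, abs=0.02)
        lo, hi = stable[0].basin
        assert hi - lo == pytest.approx(2 * np.pi, abs=0.05)

    def test_plus_sine_stable_at_pi(self):
        x = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        locks = find_lockings(LockingFunctional(dphi=x, g=np.sin(x)))
        stable = [L for L in locks if L.stable]
        assert len(stable) == 1 and stable[0].dphi == pytest.approx(np.pi, abs=0.02)

    def test_no_zero_crossing_empty(self):
        x = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        assert find_lockings(LockingFunctional(dphi=x, g=np.ones_like(x))) == []

    def test_functional_is_odd_for_identical_units(self, osc_params):
        prc = adjoint_prc(osc_params)
        phases, wave, T = limit_cycle_waveform(osc_params)
        g = locking_functional(prc, wave, 0.1, 2 * np.pi * 0.5 / T,
                               waveform_phases=phases, infinitesimal=True)
        flipped = np.interp(np.mod(-g.dphi, 2 * np.pi), g.dphi, g.g, period=2 * np.pi)
        np.testing.assert_allclose(g.g, -flipped, atol=1e-3 * np.max(np.abs(g.g)) * 10)

    def test_strong_inhibition_breaks_antiphase(self, osc_params):
        """Out-of-phase pair of stable lockings, anti-phase and in-phase unstable."""
        prc = adjoint_prc(osc_params)
        phases, wave, T = limit_cycle_waveform(osc_params)
        tgrid = phases / (2 * np.pi) * T
        nu_del = np.interp(np.mod(tgrid - osc_params.d_local, T), tgrid, wave)
        gate = (osc_params.i0 - osc_params.k_local * nu_del) > 0
        g = locking_functional(prc, wave, 0.1, 2 * np.pi * 0.5 / T,
                               gate=gate, waveform_phases=phases, infinitesimal=True)
        locks = find_lockings(g)
        stable = sorted(L.dphi for L in locks if L.stable)
        unstable = sorted(L.dphi for L in locks if not L.stable)
        assert len(stable) == 2
        assert stable[0] == pytest.approx(2 * np.pi - stable[1], abs=0.1)
        assert 0.0 < stable[0] < np.pi < stable[1]
        assert any(abs(u) < 0.1 or abs(u - 2 * np.pi) < 0.1 for u in unstable)
        assert any(abs(u - np.pi) < 0.1 for u in unstable)

    def test_weak_inhibition_antiphase_stable(self):
        p = RateModelParams(n_areas=1, i0=1.0, k_local=5.0, d_local=1.0,
                            d_cross=0.5, dt=0.01, duration=200.0)
        prc = adjoint_prc(p)
        phases, wave, T = limit_cycle_waveform(p)
        tgrid = phases / (2 * np.pi) * T
        nu_del = np.interp(np.mod(tgrid - p.d_local, T), tgrid, wave)
        gate = (p.i0 - p.k_local * nu_del) > 0
        g = locking_functional(prc, wave, 0.1, 2 * np.pi * 0.5 / T,
                               gate=gate, waveform_phases=phases, infinitesimal=True)
        stable = [L.dphi for L in find_lockings(g) if L.stable]
        assert len(stable) == 1
        assert stable[0] == pytest.approx(np.pi, abs=0.15)
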