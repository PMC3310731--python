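"""Rate-model integration, cycle detection and bifurcation structure."""

import numpy as np
import pytest
from dataclasses import replace

from effconn.rate import (RateModelParams, simulate_rate, detect_cycles,
                          bifurcation_diagram, cluster_amplitudes)


def test_fixed_point_without_feedback():
    # K = K12 = 0: pure leak toward I0, exponential relaxation
    p = RateModelParams(n_areas=1, i0=1.0, k_local=0.0, k_cross=0.0,
                        d_local=1.0, d_cross=1.0, dt=0.01, duration=30.0)
    traj = simulate_rate(p, init_history=0.2)
    assert traj.rates[-1, 0] == pytest.approx(1.0, abs=1e-6)
    # closed-form exponential at an intermediate time
    t_probe = 3.0
    i = int(t_probe / p.dt)
    expected = 1.0 + (0.2 - 1.0) * np.exp(-t_probe)
    assert traj.rates[i, 0] == pytest.approx(expected, rel=1e-2)


def test_symmetry_preservation():
    p = RateModelParams(n_areas=2, i0=1.0, k_local=20.0, k_cross=0.3,
                        d_local=1.0, d_cross=0.5, dt=0.01, duration=150.0)
    traj = simulate_rate(p, init_history=0.1)
    np.testing.assert_array_equal(traj.rates[:, 0], traj.rates[:, 1])


def test_rates_stay_nonnegative(osc_params):
    traj = simulate_rate(osc_params, init_history=0.3)
    assert (traj.rates >= 0).all()


def test_period_against_fine_step_reference(osc_params):
    """Euler at dt and at dt/10 agree on the oscillation period within 1%."""
    coarse = simulate_rate(osc_params, init_history=0.1)
    fine = simulate_rate(replace(osc_params, dt=osc_params.dt / 10), init_history=0.1)
    sel_c = coarse.times > 100
    sel_f = fine.times > 100
    Tc = detect_cycles(coarse.times[sel_c], coarse.rates[sel_c, 0]).mean_period
    Tf = detect_cycles(fine.times[sel_f], fine.rates[sel_f, 0]).mean_period
    assert Tc == pytest.approx(Tf, rel=0.01)


def test_dt_validation_rejects_large_step():
    with pytest.raises(ValueError, match="dt"):
        RateModelParams(n_areas=1, d_local=1.0, d_cross=1.0, dt=0.2)


def test_nonfinite_aborts_with_diagnostic():
    p = RateModelParams(n_areas=2, i0=1.0, k_local=20.0, k_cross=50.0,
                        d_local=1.0, d_cross=0.5, dt=0.01, duration=2000.0)
    with pytest.raises(FloatingPointError):
        simulate_rate(p, init_history=np.array([0.05, 0.4]))


def test_deterministic_given_seed(osc_params):
    a = simulate_rate(osc_params, init_history=0.1, noise_amplitude=0.05, seed=7)
    b = simulate_rate(osc_params, init_history=0.1, noise_amplitude=0.05, seed=7)
    np.testing.assert_array_equal(a.rates, b.rates)


class TestDetectCycles:
    def test_pure_sine(self):
        T = 10.0
        t = np.arange(0, 200, 0.01)
        cyc = detect_cycles(t, np.sin(2 * np.pi * t / T))
        assert cyc.oscillatory
        assert cyc.mean_period == pytest.approx(T, rel=1e-3)
        np.testing.assert_allclose(cyc.peak_amplitudes, 1.0, atol=1e-4)
        # peaks at T*(k + 1/4)
        ks = np.round(cyc.peak_times / T - 0.25)
        np.testing.assert_allclose(cyc.peak_times, T * (ks + 0.25), atol=0.02)

    def test_constant_signal_flagged(self):
        t = np.arange(0, 10, 0.01)
        cyc = detect_cycles(t, np.ones_like(t))
        assert not cyc.oscillatory
        assert cyc.peak_times.size == 0

    def test_noise_robustness(self, rng):
        T = 10.0
        t = np.arange(0, 300, 0.01)
        clean = np.sin(2 * np.pi * t / T)
        noisy = clean + 0.01 * rng.standard_normal(t.size)
        c0 = detect_cycles(t, clean)
        c1 = detect_cycles(t, noisy)
        assert c1.peak_times.size == c0.peak_times.size
        np.testing.assert_allclose(c1.peak_amplitudes, c0.peak_amplitudes, rtol=0.05)


class TestBifurcation:
    def test_cluster_amplitudes_splits_gaps(self):
        a = np.array([1.0, 1.001, 1.002, 1.5, 1.501])
        clusters = cluster_amplitudes(a, rel_tol=0.01)
        assert [c.size for c in clusters] == [3, 2]

    def test_weak_coupling_single_branch(self):
        p = RateModelParams(n_areas=2, i0=1.0, k_local=20.0, d_local=1.0,
                            d_cross=0.5, dt=0.01, duration=600.0)
        diagram = bifurcation_diagram(p, [0.1], transient_discard=300.0)
        for amps in diagram[0.1]:
            assert len(cluster_amplitudes(amps)) == 1

    def test_strong_coupling_continuous_band(self):
        p = RateModelParams(n_areas=2, i0=1.0, k_local=20.0, d_local=1.0,
                            d_cross=0.5, dt=0.01, duration=1500.0)
        diagram = bifurcation_diagram(p, [8.0], transient_discard=600.0)
        n_clusters = max(len(cluster_amplitudes(a)) for a in diagram[8.0])
        assert n_clusters >= 20

    def test_effective_entrainment_asymmetry(self):
        """Symmetric wiring, asymmetric dynamics: at intermediate coupling
        one area's peak amplitudes branch while the other's stay on a single
        branch (the laggard behaves as if driven); weak coupling keeps both
        areas simply periodic, matching the one-way-wired control."""
        sym = RateModelParams(n_areas=2, i0=1.0, k_local=20.0, d_local=1.0,
                              d_cross=0.5, dt=0.01, duration=1500.0)
        uni = replace(sym, k_cross=np.array([[0.0, 0.0], [1.0, 0.0]]))
        d_sym = bifurcation_diagram(sym, [0.3], transient_discard=700.0)[0.3]
        d_uni = bifurcation_diagram(uni, [0.3], transient_discard=700.0)[0.3]
        assert [len(cluster_amplitudes(a)) for a in d_sym] == [1, 1]
        assert [len(cluster_amplitudes(a)) for a in d_uni] == [1, 1]

        d_mid = bifurcation_diagram(sym, [5.0], transient_discard=700.0)[5.0]
        counts = sorted(len(cluster_amplitudes(a)) for a in d_mid)
        assert counts[0] <= 2 and counts[1] >= 3
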