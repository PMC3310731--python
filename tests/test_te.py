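"""Transfer-entropy estimator: exact oracle equivalence, closed forms,
invariances, and scan structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from effconn.te import (quantize, transfer_entropy, partialized_te, unbalance,
                        te_scan, surrogate_bias)
from effconn.surrogates import gen_lagged_oscillators, SurrogateSpec


def brute_force_te(x, y, tau, n):
    """Independent oracle: explicit enumeration of (y+, y, x) triples and
    literal evaluation of sum p log2 [p(y+|y,x) / p(y+|y)]."""
    triples = [(y[t + tau], y[t], x[t]) for t in range(len(x) - tau)]
    N = len(triples)
    from collections import Counter
    c3 = Counter(triples)
    c_yx = Counter((yp, xp) for _, yp, xp in triples)
    c_y = Counter(yp for _, yp, xp in triples)
    c_yy = Counter((yf, yp) for yf, yp, _ in triples)
    te = 0.0
    for (yf, yp, xp), cnt in c3.items():
        p = cnt / N
        p_cond_full = cnt / c_yx[(yp, xp)]
        p_cond_part = c_yy[(yf, yp)] / c_y[yp]
        te += p * np.log2(p_cond_full / p_cond_part)
    return te


def brute_force_pte(x, y, z, tau, n, cond_lag=0):
    from collections import Counter
    quads = [(y[t + tau], y[t], x[t], z[t + cond_lag]) for t in range(len(x) - tau)]
    N = len(quads)
    c4 = Counter(quads)
    c_yxz = Counter((yp, xp, zp) for _, yp, xp, zp in quads)
    c_yz = Counter((yp, zp) for _, yp, xp, zp in quads)
    c_yyz = Counter((yf, yp, zp) for yf, yp, xp, zp in quads)
    te = 0.0
    for (yf, yp, xp, zp), cnt in c4.items():
        p = cnt / N
        te += p * np.log2((cnt / c_yxz[(yp, xp, zp)]) / (c_yyz[(yf, yp, zp)] / c_yz[(yp, zp)]))
    return te


def test_oracle_equivalence_100_random_cases():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(2, 5))
        length = int(rng.integers(10, 51))
        tau = int(rng.integers(1, 4))
        x = rng.integers(0, n, length)
        y = rng.integers(0, n, length)
        got = transfer_entropy(x, y, tau, n_bins=n).value
        want = brute_force_te(x, y, tau, n)
        assert got == pytest.approx(want, abs=1e-12)


def test_pte_oracle_equivalence():
    rng = np.random.default_rng(1)
    for _ in range(30):
        n = int(rng.integers(2, 4))
        length = int(rng.integers(15, 51))
        tau = int(rng.integers(1, 4))
        cond_lag = int(rng.integers(0, tau + 1))
        x, y, z = (rng.integers(0, n, length) for _ in range(3))
        got = partialized_te(x, y, z, tau, n_bins=n, cond_lag=cond_lag).value
        want = brute_force_pte(x, y, z, tau, n, cond_lag)
        assert got == pytest.approx(want, abs=1e-12)


def test_copy_channel_is_log2n():
    rng = np.random.default_rng(2)
    for n in (2, 3, 4):
        x = rng.integers(0, n, 100_000)
        y = np.roll(x, 1)
        te = transfer_entropy(x, y, 1, n_bins=n).value
        assert te == pytest.approx(np.log2(n), rel=0.01)


def test_independent_series_near_zero():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 2, 100_000)
    y = rng.integers(0, 2, 100_000)
    assert transfer_entropy(x, y, 1).value <= 0.01


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_te_nonnegative(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, 300)
    y = rng.integers(0, 3, 300)
    assert transfer_entropy(x, y, 2, n_bins=3).value >= 0.0
    z = rng.integers(0, 3, 300)
    assert partialized_te(x, y, z, 2, n_bins=3).value >= 0.0


def test_relabeling_invariance():
    rng = np.random.default_rng(4)
    n = 4
    x = rng.integers(0, n, 5000)
    y = (x + rng.integers(0, 2, 5000)) % n
    base = transfer_entropy(x, y, 2, n_bins=n).value
    perm = rng.permutation(n)
    assert transfer_entropy(perm[x], y, 2, n_bins=n).value == pytest.approx(base, abs=1e-12)
    assert transfer_entropy(x, perm[y], 2, n_bins=n).value == pytest.approx(base, abs=1e-12)


class TestQuantize:
    def test_single_bin(self):
        s = quantize(np.array([1.0, 5.0, -2.0]), 1)
        np.testing.assert_array_equal(s.symbols, 0)

    def test_edge_arithmetic(self):
        s = quantize(np.array([0.0, 1.0, 2.0, 3.0]), 2)
        np.testing.assert_array_equal(s.symbols, [0, 0, 1, 1])

    def test_top_edge_inclusive(self):
        s = quantize(np.array([0.0, 1.0]), 4)
        assert s.symbols[-1] == 3

    def test_occupancy_matches_histogram(self, rng):
        x = rng.standard_normal(20_000)
        s = quantize(x, 8)
        hist, _ = np.histogram(x, bins=s.bin_edges)
        # np.histogram and quantize agree up to edge-rounding of single samples
        np.testing.assert_allclose(np.bincount(s.symbols, minlength=8), hist, atol=1)

    def test_constant_signal_warns(self):
        with pytest.warns(UserWarning):
            quantize(np.ones(10), 3)


class TestUnbalance:
    def test_symmetric_zero(self):
        assert unbalance(0.2, 0.2).u == 0.0

    def test_one_sided(self):
        assert unbalance(0.3, 0.0).u == 1.0

    def test_arithmetic(self):
        assert unbalance(0.3, 0.1).u == pytest.approx(0.5)

    def test_undefined_when_both_zero(self):
        r = unbalance(0.0, 0.0)
        assert not r.defined

    def test_bounded(self, rng):
        for _ in range(50):
            a, b = rng.random(2)
            assert abs(unbalance(a, b).u) <= 1.0


def test_scan_peaks_at_construction_lag_and_repeats_with_period():
    """Leader->laggard TE peaks at the imposed lag delta (and again one
    period later), and dominates the reverse direction there."""
    spec = SurrogateSpec(seed=5, n_cycles=500, coupling=0.95, obs_noise=0.01)
    _, lead, lagg, truth = gen_lagged_oscillators(spec)
    T_samp = spec.samples_per_cycle
    delta = int(truth["lag_samples"])
    scan = te_scan(lead, lagg, [4], range(1, int(2.2 * T_samp)))
    peak_fwd = scan.peak_lag_xy[4]
    assert abs(peak_fwd - delta) <= 2
    curve = scan.te_xy[0]
    taus = scan.tau_grid
    second = taus[np.argmax(np.where((taus > delta + T_samp // 2)
                                     & (taus <= delta + 3 * T_samp // 2), curve, -1))]
    assert abs(second - (delta + T_samp)) <= 2
    i_delta = np.argmin(np.abs(taus - delta))
    assert scan.te_xy[0][i_delta] > scan.te_yx[0][i_delta]
    assert scan.unbalance[0][i_delta] > 0


def test_te_grows_with_bin_count_on_fluctuating_surrogate():
    spec = SurrogateSpec(seed=6, n_cycles=400)
    _, lead, lagg, truth = gen_lagged_oscillators(spec)
    tau = int(round(truth["lag_samples"]))
    vals = [transfer_entropy(quantize(lead, n), quantize(lagg, n), tau).value
            for n in (2, 4, 8)]
    assert vals[0] < vals[1] < vals[2]


def test_surrogate_bias_bounds_independent_te():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 4, 20_000)
    y = rng.integers(0, 4, 20_000)
    bias = surrogate_bias(x, y, 3, seed=0)
    assert transfer_entropy(x, y, 3).value <= 3 * bias
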