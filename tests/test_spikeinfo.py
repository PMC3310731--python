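"""Spike digitization, pairing conventions, entropy/MI closed forms and
finite-size debiasing."""

import numpy as np
import pytest

from effconn.spikeinfo import digitize, pair_codes, info_estimate, debias, PairedCode
from effconn.surrogates import gen_binary_channel, binary_entropy, bsc_mutual_information


class TestDigitize:
    def test_every_cycle_firing(self):
        starts = np.arange(0.0, 101.0, 10.0)
        spikes = np.column_stack([np.zeros(10), starts[:-1] + 5.0])
        code = digitize(spikes, starts)
        np.testing.assert_array_equal(code.streams[0], 1)

    def test_silent_neuron_all_zero(self):
        starts = np.arange(0.0, 101.0, 10.0)
        spikes = np.empty((0, 2))
        code = digitize(spikes, starts, neuron_ids=[7])
        np.testing.assert_array_equal(code.streams[7], 0)
        est = info_estimate(pair_codes(code.streams[7], code.streams[7], "source-leads"))
        assert est.h_source == 0.0 and np.isnan(est.efficiency)

    def test_multiple_spikes_clipped(self):
        starts = np.array([0.0, 10.0, 20.0])
        spikes = np.array([[0, 1.0], [0, 2.0], [0, 15.0]])
        code = digitize(spikes, starts)
        np.testing.assert_array_equal(code.streams[0], [1, 1])
        assert code.clipped == 1

    def test_thinned_periodic_rate(self, rng):
        starts = np.arange(0.0, 6001.0, 10.0)
        fire = rng.random(600) < 1 / 6
        times = starts[:-1][fire] + 3.0
        spikes = np.column_stack([np.zeros(times.size), times])
        code = digitize(spikes, starts, neuron_ids=[0])
        assert code.streams[0].mean() == pytest.approx(1 / 6, abs=0.05)


class TestPairing:
    def test_identity_source_leads(self):
        s = np.array([1, 0, 1, 1, 0], dtype=np.int8)
        pc = pair_codes(s, s, "source-leads")
        est = info_estimate(pc)
        assert est.efficiency == pytest.approx(1.0)

    def test_shift_convention_recovers_identity(self):
        rng = np.random.default_rng(0)
        s = (rng.random(2000) < 0.3).astype(np.int8)
        t = np.zeros_like(s)
        t[1:] = s[:-1]              # effect lands one target cycle later
        est = info_estimate(pair_codes(s, t, "source-lags"))
        assert est.efficiency == pytest.approx(1.0)

    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(1)
        s = (rng.random(5000) < 0.3).astype(np.int8)
        t = (rng.random(5000) < 0.3).astype(np.int8)
        for role in ("source-leads", "source-lags"):
            assert info_estimate(pair_codes(s, t, role)).mi < 0.002

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            pair_codes(np.zeros(3, np.int8), np.zeros(3, np.int8), "sideways")


class TestClosedForms:
    def test_sparse_bernoulli_entropy_and_lossless_efficiency(self):
        src, tgt, truth = gen_binary_channel(1 / 6, 0.0, 100_000, seed=0)
        est = info_estimate(pair_codes(src, tgt, "source-leads"))
        assert truth["H_source"] == pytest.approx(0.650, abs=0.001)
        assert est.h_source == pytest.approx(truth["H_source"], abs=0.01)
        assert est.efficiency == pytest.approx(1.0)

    def test_bsc_mutual_information(self):
        src, tgt, truth = gen_binary_channel(0.5, 0.1, 200_000, seed=1)
        est = info_estimate(pair_codes(src, tgt, "source-leads"))
        want = 1.0 - binary_entropy(0.1)
        assert want == pytest.approx(0.531, abs=0.001)
        assert est.mi == pytest.approx(want, rel=0.02)

    def test_full_noise_zero_mi(self):
        src, tgt, _ = gen_binary_channel(0.5, 0.5, 100_000, seed=2)
        est = info_estimate(pair_codes(src, tgt, "source-leads"))
        assert est.mi < 0.001

    def test_efficiency_bounds(self, rng):
        for _ in range(20):
            s = (rng.random(3000) < rng.uniform(0.1, 0.9)).astype(np.int8)
            t = (rng.random(3000) < rng.uniform(0.1, 0.9)).astype(np.int8)
            est = info_estimate(pair_codes(s, t, "source-leads"))
            assert 0.0 <= est.efficiency <= 1.0
            assert est.mi <= min(est.h_source, est.h_target) + 1e-9


class TestDebias:
    def test_bsc_debiasing_tightens_estimate(self):
        src, tgt, truth = gen_binary_channel(0.5, 0.1, 100_000, seed=3)
        pc = pair_codes(src, tgt, "source-leads")
        est = debias(pc, seed=0)
        assert est.debiased_mi == pytest.approx(truth["MI"], rel=0.02)
        assert est.fit["coefficients"][-1] == pytest.approx(est.debiased_mi)

    def test_independent_pair_debiases_to_zero(self):
        rng = np.random.default_rng(4)
        s = (rng.random(50_000) < 0.4).astype(np.int8)
        t = (rng.random(50_000) < 0.4).astype(np.int8)
        est = debias(pair_codes(s, t, "source-leads"), seed=0)
        assert abs(est.debiased_mi) <= 0.005

    def test_plugin_bias_positive_and_shrinking(self):
        """Raw plug-in MI of independent streams is biased upward, more so
        at small sample sizes (true MI is exactly zero)."""
        rng = np.random.default_rng(6)
        def raw_mi(n):
            vals = []
            for _ in range(40):
                s = (rng.random(n) < 0.4).astype(np.int8)
                t = (rng.random(n) < 0.4).astype(np.int8)
                vals.append(info_estimate(pair_codes(s, t, "source-leads")).mi)
            return np.mean(vals)
        small, large = raw_mi(100), raw_mi(10_000)
        assert small > large > 0.0
        assert small > 5 * large
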