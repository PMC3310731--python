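"""Seeded surrogate generators with known ground truth.

These generators emulate the statistical structure the analysis stack
assumes — sparsely fluctuating coupled oscillations, binary per-cycle spike
codes through a known channel, and small Markov chains with a purely
indirect causal path — without simulating the full dynamical models.  Every
generator is bit-reproducible from its seed and returns its ground truth in
machine-readable form alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "SurrogateSpec",
    "gen_lagged_oscillators",
    "gen_binary_channel",
    "gen_markov_chain_triplet",
    "binary_entropy",
    "bsc_mutual_information",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Two coupled oscillator channels with directed amplitude coupling.

    The leader is a sinusoid of period ``period`` whose cycle amplitudes
    follow an AR(1) process (coefficient ``ar_coeff``, innovation sd
    ``amp_sigma``).  The laggard is the same sinusoid delayed by ``lag``
    with amplitudes copied from the leader, attenuated by ``coupling`` and
    corrupted by independent cycle noise; ``coupling = 0`` gives fully
    independent amplitude streams.  White observation noise of sd
    ``obs_noise`` is added to both channels.
    """

    period: float = 10.0
    lag: float = 2.5
    coupling: float = 0.9
    ar_coeff: float = 0.8
    amp_sigma: float = 0.25
    period_jitter: float = 0.03
    obs_noise: float = 0.02
    n_cycles: int = 400
    samples_per_cycle: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lag < self.period:
            raise ValueError("lag must lie in (0, period)")
        if self.n_cycles < 10:
            raise ValueError("need at least 10 cycles")


def _ar1(n: int, rho: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(n) * sigma
    a = np.empty(n)
    a[0] = eps[0] / np.sqrt(max(1e-12, 1 - rho**2))
    for k in range(1, n):
        a[k] = rho * a[k - 1] + eps[k]
    return a


def _phase_track(n_cycles: int, T: float, jitter: float, rng, phase0: float = 0.0):
    """Cycle start times with jittered cycle lengths, and the piecewise-linear
    unwrapped phase evaluated at time t (2*pi per cycle)."""
    lengths = T * (1.0 + jitter * rng.standard_normal(n_cycles + 4))
    lengths = np.clip(lengths, 0.5 * T, 1.5 * T)
    starts = np.concatenate([[0.0], np.cumsum(lengths)]) - phase0 / (2 * np.pi) * T

    def phi(t):
        base = 2 * np.pi * (np.arange(starts.size) - 0.0)
        return np.interp(t, starts, base)

    def cycle_idx(t):
        return np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_cycles + 3)

    return phi, cycle_idx


def gen_lagged_oscillators(spec: SurrogateSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Generate (times, leader, laggard) plus a ground-truth dict.

    Cycle lengths of each rhythm fluctuate (relative sd ``period_jitter``).
    With ``coupling > 0`` the laggard is the leader's rhythm delayed by
    ``lag`` with attenuated, noise-corrupted copies of its cycle
    amplitudes; with ``coupling = 0`` the laggard carries its own
    independent phase track (random initial phase) and amplitudes, so the
    two channels are fully independent.
    """
    rng = np.random.default_rng(spec.seed)
    T, delta = spec.period, spec.lag
    dt = T / spec.samples_per_cycle
    n_samp = spec.n_cycles * spec.samples_per_cycle
    t = dt * np.arange(n_samp)

    amps = _ar1(spec.n_cycles + 4, spec.ar_coeff, spec.amp_sigma, rng)
    cyc_noise = rng.standard_normal(spec.n_cycles + 4) * spec.amp_sigma * 0.3
    phi_L, idx_L = _phase_track(spec.n_cycles, T, spec.period_jitter, rng)
    lead = (1.0 + amps[idx_L(t)]) * np.sin(phi_L(t))

    if spec.coupling > 0:
        # same rhythm delayed; amplitudes copied (attenuated, noisy)
        amp_lag = spec.coupling * amps[idx_L(t - delta)] + cyc_noise[idx_L(t - delta)]
        lagg = (1.0 + amp_lag) * np.sin(phi_L(t - delta))
    else:
        own = _ar1(spec.n_cycles + 4, spec.ar_coeff, spec.amp_sigma, rng)
        phi_I, idx_I = _phase_track(spec.n_cycles, T, spec.period_jitter, rng,
                                    phase0=rng.uniform(0, 2 * np.pi))
        lagg = (1.0 + own[idx_I(t)]) * np.sin(phi_I(t))

    lead = lead + rng.standard_normal(n_samp) * spec.obs_noise
    lagg = lagg + rng.standard_normal(n_samp) * spec.obs_noise
    truth = {
        "direction": (0, 1) if spec.coupling > 0 else None,
        "lag_time": delta,
        "lag_samples": delta / dt,
        "period": T,
        "dt": dt,
        "spec": asdict(spec),
    }
    return t, lead, lagg, truth


def binary_entropy(p: float) -> float:
    """H2(p) in bits, with 0 log 0 = 0."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def bsc_mutual_information(p_fire: float, flip_prob: float) -> float:
    """Exact MI (bits/use) of a binary symmetric channel with Bernoulli(p_fire) input."""
    q = flip_prob
    p1 = p_fire * (1 - q) + (1 - p_fire) * q     # P(target = 1)
    return binary_entropy(p1) - binary_entropy(q)


def gen_binary_channel(
    p_fire: float,
    flip_prob: float,
    n_cycles: int,
    role: str = "source-leads",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Bernoulli source stream through a binary symmetric channel.

    The target stream is the source passed through a BSC with the given flip
    probability, aligned per ``role``: for ``source-lags`` the effect is
    written one cycle later in the target stream (the pairing convention
    then has to shift it back; see ``spikeinfo.pair_codes``).
    Returns (source, target, truth) with closed-form H and MI in the truth.
    """
    if not 0 < p_fire < 1:
        raise ValueError("p_fire must be in (0, 1)")
    if role not in ("source-leads", "source-lags"):
        raise ValueError("role must be 'source-leads' or 'source-lags'")
    rng = np.random.default_rng(seed)
    src = (rng.random(n_cycles) < p_fire).astype(np.int8)
    flips = (rng.random(n_cycles) < flip_prob).astype(np.int8)
    out = src ^ flips
    if role == "source-lags":
        tgt = np.zeros(n_cycles, dtype=np.int8)
        tgt[1:] = out[:-1]
    else:
        tgt = out
    truth = {
        "H_source": binary_entropy(p_fire),
        "MI": bsc_mutual_information(p_fire, flip_prob),
        "efficiency": (bsc_mutual_information(p_fire, flip_prob) / binary_entropy(p_fire)
                       if 0 < p_fire < 1 else np.nan),
        "p_fire": p_fire,
        "flip_prob": flip_prob,
        "role": role,
    }
    return src, tgt, truth


def _row_stochastic(n: int, rng: np.random.Generator, sharpness: float = 6.0) -> np.ndarray:
    """Random row-stochastic matrix with a dominant diagonal-shifted structure,
    so each hop of the chain is strongly but not deterministically informative."""
    m = rng.random((n, n)) + sharpness * np.eye(n)[:, np.roll(np.arange(n), 1)]
    return m / m.sum(axis=1, keepdims=True)


def gen_markov_chain_triplet(
    n_symbols: int,
    tau: int,
    length: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Three symbol series with the purely indirect chain x -> z -> y.

    ``x`` is i.i.d. uniform; ``z_t`` is drawn from transition matrix ``A``
    applied to ``x_{t - tau}``; ``y_t`` from matrix ``B`` applied to
    ``z_{t - tau}``.  There is no direct x -> y edge: all influence of x on
    y is routed through z with a two-hop latency of ``2 tau``.

    The truth dict carries A, B and the closed-form TE(x -> y) at lag
    ``2 tau`` (equal to the mutual information of the composed channel AB
    under a uniform input, because x is memoryless).
    """
    rng = np.random.default_rng(seed)
    n = n_symbols
    A = _row_stochastic(n, rng)
    B = _row_stochastic(n, rng)
    x = rng.integers(0, n, size=length)
    z = np.empty(length, dtype=np.int64)
    y = np.empty(length, dtype=np.int64)
    u_z = rng.random(length)
    u_y = rng.random(length)
    cumA = np.cumsum(A, axis=1)
    cumB = np.cumsum(B, axis=1)
    for tpos in range(length):
        zsrc = x[tpos - tau] if tpos >= tau else rng.integers(0, n)
        z[tpos] = np.searchsorted(cumA[zsrc], u_z[tpos], side="right")
        ysrc = z[tpos - tau] if tpos >= tau else rng.integers(0, n)
        y[tpos] = np.searchsorted(cumB[ysrc], u_y[tpos], side="right")
    z = np.minimum(z, n - 1)
    y = np.minimum(y, n - 1)

    # analytic TE(x -> y) at lag 2 tau: x memoryless => y_t independent of
    # (x_t, y_{t+2tau}); TE reduces to the MI of the channel C = A @ B.
    C = A @ B
    p_y = C.mean(axis=0)                       # uniform input
    mi = 0.0
    for i in range(n):
        for j in range(n):
            pij = C[i, j] / n
            if pij > 0:
                mi += pij * np.log2(C[i, j] / p_y[j])
    truth = {
        "A": A,
        "B": B,
        "te_xy_analytic": float(mi),
        "lag_xy": 2 * tau,
        "tau": tau,
        "n_symbols": n,
    }
    return x, z, y, truth
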