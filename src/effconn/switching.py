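"""Phase-targeted switching of effective-connectivity direction.

In a symmetry-broken out-of-phase locked state the phase difference sits in
the basin of one of two mirror-image stable lockings.  A brief pulse applied
to one area at phase ``phi`` of its ongoing cycle kicks the phase difference
by the (finite-pulse) response ``Delta(phi, A)``; if the kicked difference
lands in the basin of the other stable locking, the leader/laggard roles —
and with them the direction of the effective motif — flip.  The phase
intervals where this happens are predicted from the locking functional and
the response curve alone, and verified here by direct pulsed simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .rate import RateModelParams, simulate_rate, detect_cycles
from .phase import (ResponseCurve, LockingFunctional, Locking, find_lockings,
                    empiric_phase, measured_lag)

__all__ = [
    "SwitchPrediction",
    "SwitchExperiment",
    "TwoAreaRateModel",
    "predict_intervals",
    "apply_pulse",
    "success_histogram",
    "locking_labels",
]


@dataclass
class SwitchPrediction:
    role: str                                  # "leader" | "laggard"
    strength: float
    intervals: list[tuple[float, float]]       # sub-intervals of [0, 2*pi), end > start (may wrap)
    source_locking: float
    target_locking: float | None
    success_mask: np.ndarray | None = None     # per-grid-phase predicted success
    phase_grid: np.ndarray | None = None

    def contains(self, phi: float) -> bool:
        phi = float(np.mod(phi, 2 * np.pi))
        for a, b in self.intervals:
            if a <= b:
                if a <= phi <= b:
                    return True
            elif phi >= a or phi <= b:
                return True
        return False


@dataclass
class SwitchExperiment:
    phase_grid: np.ndarray
    trials: int
    success_frequency: np.ndarray
    settled_labels: list[list[str]]
    prediction: SwitchPrediction | None = None


def _basin_of(lockings: list[Locking], dphi: float) -> float | None:
    """Stable locking whose basin contains ``dphi`` (None if between basins)."""
    dphi = np.mod(dphi, 2 * np.pi)
    for L in lockings:
        if not L.stable or L.basin is None:
            continue
        lo, hi = L.basin
        x = dphi
        if x < lo:
            x += 2 * np.pi
        if lo <= x <= hi:
            return L.dphi
    return None


def predict_intervals(
    g: LockingFunctional,
    response: ResponseCurve,
    strength: float,
    role: str,
    current_locking: float | None = None,
    phase_grid: np.ndarray | None = None,
    infinitesimal: bool = False,
) -> SwitchPrediction:
    """Application-phase intervals for which a pulse flips the locking.

    ``role`` names the perturbed area relative to the current locking:
    kicking the laggard (phase behind) advances it and *reduces* the
    leader-laggard phase difference; kicking the leader increases it.  The
    response curve is sampled on ``phase_grid`` (defaults to its own grid);
    with ``infinitesimal=True`` the curve is an infinitesimal PRC and the
    kick is ``strength * Z(phi)``, otherwise the curve is used as measured.
    """
    if role not in ("leader", "laggard"):
        raise ValueError("role must be 'leader' or 'laggard'")
    lockings = find_lockings(g)
    stable = [L for L in lockings if L.stable]
    if current_locking is None:
        if not stable:
            raise ValueError("no stable locking found")
        current_locking = stable[0].dphi
    cur_basin = _basin_of(lockings, current_locking)
    if len(stable) < 2:
        import warnings
        warnings.warn("monostable locking functional: no switching possible", stacklevel=2)
        return SwitchPrediction(role=role, strength=strength, intervals=[],
                                source_locking=current_locking, target_locking=None)

    # sign of the kick on dphi = phi_2 - phi_1: the perturbed area's phase
    # advances by Delta(phi) >= or <= 0; whether that adds to or subtracts
    # from the leader-laggard difference depends on which role it plays.
    # Writing the difference as "leader minus laggard" = d in (0, pi):
    # kicking the laggard subtracts Delta from d, kicking the leader adds.
    d_cur = np.mod(current_locking, 2 * np.pi)
    leader_is_2 = d_cur < np.pi   # dphi = phi2 - phi1 in (0, pi): area 2 ahead
    perturb_area_2 = (role == "leader") == leader_is_2
    sign = +1.0 if perturb_area_2 else -1.0

    grid = phase_grid if phase_grid is not None else response.phases
    delta = response.interp(grid) * (strength if infinitesimal else 1.0)
    kicked = np.mod(d_cur + sign * delta, 2 * np.pi)
    success = np.zeros(grid.size, dtype=bool)
    target = None
    for i, dk in enumerate(kicked):
        b = _basin_of(lockings, dk)
        if b is not None and cur_basin is not None and not np.isclose(b, cur_basin):
            success[i] = True
            target = b
    intervals = _mask_to_intervals(grid, success)
    return SwitchPrediction(role=role, strength=strength, intervals=intervals,
                            source_locking=d_cur, target_locking=target,
                            success_mask=success, phase_grid=grid)


def _mask_to_intervals(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    if not mask.any():
        return []
    if mask.all():
        return [(0.0, 2 * np.pi)]
    n = grid.size
    intervals = []
    i = 0
    # start from a False position to handle wrap-around
    start0 = int(np.argmin(mask))
    order = [(start0 + k) % n for k in range(n)]
    run_start = None
    for idx in order:
        if mask[idx] and run_start is None:
            run_start = grid[idx]
        elif not mask[idx] and run_start is not None:
            intervals.append((float(run_start), float(grid[idx - 1] if idx > 0 else grid[-1])))
            run_start = None
    if run_start is not None:
        intervals.append((float(run_start), float(grid[order[-1]])))
    return intervals


class TwoAreaRateModel:
    """Experiment handle: a two-area rate motif settled in an out-of-phase locking.

    Provides the classification primitives the switching experiments need:
    run (optionally pulsed) simulations and classify the settled locking
    from the measured inter-areal lag sign ("0-leads" / "1-leads"; "none"
    for in-/anti-phase or non-locked states, decided with a tolerance of
    5% of a period).
    """

    def __init__(self, params: RateModelParams, init_history=None,
                 noise_amplitude: float = 0.0, settle_time: float = 200.0):
        if params.n_areas != 2:
            raise ValueError("TwoAreaRateModel requires n_areas == 2")
        self.params = params
        self.init_history = init_history if init_history is not None else np.array([0.05, 0.08])
        self.noise_amplitude = noise_amplitude
        self.settle_time = settle_time

    def run(self, duration: float, pulse=None, seed: int | None = None):
        p = _dc_replace(self.params, duration=duration)
        return simulate_rate(p, init_history=self.init_history,
                             noise_amplitude=self.noise_amplitude, seed=seed, pulse=pulse)

    def classify_window(self, traj, t_lo: float, t_hi: float) -> str:
        sel = (traj.times >= t_lo) & (traj.times <= t_hi)
        x0 = traj.rates[sel, 0]
        x1 = traj.rates[sel, 1]
        cyc = detect_cycles(traj.times[sel], x0)
        if not cyc.oscillatory:
            return "none"
        lag = measured_lag(x0, x1, self.params.dt, cyc.mean_period)
        if abs(lag) < 0.05 * cyc.mean_period or abs(abs(lag) - cyc.mean_period / 2) < 0.05 * cyc.mean_period:
            return "none"
        return "0-leads" if lag > 0 else "1-leads"


def apply_pulse(
    model: TwoAreaRateModel,
    area: int,
    phi_apply: float,
    strength: float,
    seed: int | None = None,
    skip_cycles: int = 10,
    classify_cycles: int = 40,
) -> tuple[str, str, int]:
    """Inject one pulse at the given phase of ``area``'s ongoing cycle.

    Returns (label_before, label_after, latency_cycles): the settled motif
    labels before the pulse and after discarding ``skip_cycles`` cycles, and
    the number of cycles until the post-pulse label chain stabilizes at its
    settled value (0 when the first post-pulse cycle already matches).

    Models providing their own ``apply_pulse`` method (the spiking-network
    handle) are dispatched to it.
    """
    if hasattr(model, "apply_pulse"):
        return model.apply_pulse(area, phi_apply, strength, seed=seed,
                                 skip_cycles=skip_cycles,
                                 classify_cycles=classify_cycles)
    settle = model.settle_time
    probe = model.run(settle + 250.0, seed=seed)
    sel = probe.times >= settle
    cyc = detect_cycles(probe.times[sel], probe.rates[sel, area])
    if not cyc.oscillatory:
        raise ValueError("model is not oscillating")
    T = cyc.mean_period
    # pulse late enough that the pre-pulse window classifies reliably
    late = cyc.start_times[cyc.start_times > settle + 30 * T]
    if late.size == 0:
        raise ValueError("baseline too short to place the pulse")
    start = late[0]
    t_pulse = start + np.mod(phi_apply, 2 * np.pi) / (2 * np.pi) * T

    total = t_pulse + (skip_cycles + classify_cycles + 5) * T
    traj = model.run(total, pulse=(t_pulse, area, strength), seed=seed)
    before = model.classify_window(traj, settle, t_pulse - model.params.dt)
    after = model.classify_window(traj, t_pulse + skip_cycles * T, t_pulse + (skip_cycles + classify_cycles) * T)

    # latency: first post-pulse cycle from which the per-cycle label stays settled
    latency = 0
    for k in range(skip_cycles + classify_cycles):
        lab = model.classify_window(traj, t_pulse + k * T, t_pulse + (k + 4) * T)
        if lab == after:
            latency = k
            break
    return before, after, latency


def success_histogram(
    model: TwoAreaRateModel,
    area: int,
    strength: float,
    phase_grid: int | np.ndarray = 50,
    trials: int = 1,
    seed: int | None = None,
    prediction: SwitchPrediction | None = None,
) -> SwitchExperiment:
    """Per-phase frequency of successful direction switches.

    A trial succeeds when the settled post-pulse label differs from the
    pre-pulse label (both out-of-phase labels; degenerate outcomes count as
    failures).  For the noiseless rate model trials are redundant and the
    frequencies are exactly 0 or 1.
    """
    if np.isscalar(phase_grid):
        grid = np.linspace(0, 2 * np.pi, int(phase_grid), endpoint=False)
    else:
        grid = np.asarray(phase_grid, float)
    rng = np.random.default_rng(seed)
    freq = np.zeros(grid.size)
    labels: list[list[str]] = []
    for i, phi in enumerate(grid):
        lab_i = []
        succ = 0
        for _ in range(trials):
            s = int(rng.integers(2**31)) if model.noise_amplitude > 0 else None
            before, after, _ = apply_pulse(model, area, phi, strength, seed=s)
            ok = before != "none" and after != "none" and after != before
            succ += ok
            lab_i.append(after)
        freq[i] = succ / trials
        labels.append(lab_i)
    return SwitchExperiment(phase_grid=grid, trials=trials, success_frequency=freq,
                            settled_labels=labels, prediction=prediction)


class TwoAreaNetworkModel:
    """Switching-experiment handle for the two-area spiking network.

    Uses frozen background noise: baseline and pulsed runs share the seed,
    so the Poisson input realization is identical and the pulse is the
    only difference.  The pulse is a rectangular current of duration
    ``pulse_ms`` (about a twentieth of a period) injected into every
    neuron of the chosen area.
    """

    def __init__(self, graph, settle_time: float = 500.0, pulse_ms: float = 1.0):
        self.graph = graph
        self.settle_time = settle_time
        self.pulse_ms = pulse_ms
        self.noise_amplitude = 1.0      # stochastic: trials draw fresh seeds

    def run(self, duration: float, pulse=None, seed: int | None = None):
        from .spiking import simulate_network
        net_pulse = None
        if pulse is not None:
            t_pulse, area, amp = pulse
            net_pulse = (t_pulse, t_pulse + self.pulse_ms, amp, area)
        _, rec = simulate_network(self.graph, duration, seed=seed or 0, pulse=net_pulse)
        return rec

    def classify_window(self, rec, t_lo: float, t_hi: float) -> str:
        sel = (rec.times >= t_lo) & (rec.times <= t_hi)
        if sel.sum() < 16:
            return "none"
        x0 = rec.lfp[sel, 0]
        x1 = rec.lfp[sel, 1]
        dt = rec.times[1] - rec.times[0]
        cyc = detect_cycles(rec.times[sel], x0)
        if not cyc.oscillatory:
            return "none"
        lag = measured_lag(x0, x1, dt, cyc.mean_period)
        if abs(lag) < 0.05 * cyc.mean_period or abs(abs(lag) - cyc.mean_period / 2) < 0.05 * cyc.mean_period:
            return "none"
        return "0-leads" if lag > 0 else "1-leads"

    def apply_pulse(self, area: int, phi_apply: float, strength: float,
                    seed: int | None = None, skip_cycles: int = 10,
                    classify_cycles: int = 40) -> tuple[str, str, int]:
        seed = 0 if seed is None else seed
        settle = self.settle_time
        probe = self.run(settle + 400.0, seed=seed)
        sel = probe.times >= settle
        cyc = detect_cycles(probe.times[sel], probe.lfp[sel, area])
        if not cyc.oscillatory:
            raise ValueError("network is not oscillating")
        T = cyc.mean_period
        late = cyc.start_times[cyc.start_times > settle + 5 * T]
        if late.size == 0:
            if cyc.start_times.size < 3:
                raise ValueError("baseline too short to place the pulse")
            late = cyc.start_times[-2:]
        start = late[0]
        t_pulse = start + np.mod(phi_apply, 2 * np.pi) / (2 * np.pi) * T
        total = t_pulse + (skip_cycles + classify_cycles + 5) * T
        rec = self.run(total, pulse=(t_pulse, area, strength), seed=seed)
        before = self.classify_window(rec, settle, t_pulse - 1.0)
        after = self.classify_window(rec, t_pulse + skip_cycles * T,
                                     t_pulse + (skip_cycles + classify_cycles) * T)
        return before, after, 0


def locking_labels(
    times: np.ndarray,
    x0: np.ndarray,
    x1: np.ndarray,
    window_cycles: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle locking-state labels (+1: area0 leads, -1: area1 leads, 0: other).

    Returns (cycle_start_times, labels).  Used to build valid-epoch masks:
    transfer entropy must be sampled within one locking configuration, with
    transients after label changes dropped.
    """
    dt = times[1] - times[0]
    cyc = detect_cycles(times, x0)
    if not cyc.oscillatory:
        return np.array([]), np.array([])
    T = cyc.mean_period
    starts = cyc.start_times
    labels = np.zeros(starts.size, dtype=int)
    for k, t0 in enumerate(starts):
        sel = (times >= t0) & (times <= t0 + window_cycles * T)
        if sel.sum() < 8:
            continue
        try:
            lag = measured_lag(x0[sel], x1[sel], dt, T)
        except ValueError:
            continue
        if abs(lag) < 0.05 * T or abs(abs(lag) - T / 2) < 0.05 * T:
            labels[k] = 0
        else:
            labels[k] = 1 if lag > 0 else -1
    return starts, labels


def epoch_mask(
    times: np.ndarray,
    starts: np.ndarray,
    labels: np.ndarray,
    drop_after_change: int = 5,
) -> np.ndarray:
    """Valid-sample mask keeping epochs of the dominant locking label.

    Cycles within ``drop_after_change`` cycles after any label change are
    dropped, as are cycles with degenerate (0) labels.
    """
    mask = np.zeros(times.size, dtype=bool)
    if starts.size == 0:
        return mask
    nonzero = labels[labels != 0]
    if nonzero.size == 0:
        return mask
    vals, counts = np.unique(nonzero, return_counts=True)
    dominant = vals[np.argmax(counts)]
    ok_cycle = labels == dominant
    # drop cycles too close after a change
    change = np.nonzero(np.diff(labels) != 0)[0]
    for c in change:
        ok_cycle[c + 1 : c + 1 + drop_after_change] = False
    for k in range(starts.size - 1):
        if ok_cycle[k]:
            mask[(times >= starts[k]) & (times < starts[k + 1])] = True
    if ok_cycle[-1]:
        mask[times >= starts[-1]] = True
    return mask
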