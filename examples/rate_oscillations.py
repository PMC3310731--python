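"""Delayed-inhibition rate model: oscillation onset and out-of-phase locking.

Simulates two symmetrically coupled rate units in the weak-coupling regime,
detects oscillation cycles, and measures the inter-areal lag.  The printed
lag fraction strictly between 0 and 0.5 is the signature of spontaneous
symmetry breaking: one area leads although the wiring is symmetric.
"""

import numpy as np

from effconn import rate_params, REGIMES, simulate_rate, detect_cycles, measured_lag

params = rate_params("weak", duration=1500.0)
traj = simulate_rate(params, init_history=np.array([0.01, 0.03]),
                     noise_amplitude=REGIMES["weak"].noise_amplitude, seed=0)

sel = traj.times > 500
cycles = detect_cycles(traj.times[sel], traj.rates[sel, 0])
lag = measured_lag(traj.rates[sel, 0], traj.rates[sel, 1], params.dt, cycles.mean_period)

print(f"mean oscillation period  T = {cycles.mean_period:.2f} time units")
print(f"cycles detected          {cycles.peak_times.size}")
print(f"inter-areal lag          {lag:+.2f} ({abs(lag) / cycles.mean_period:.2f} T)")
leader = 0 if lag > 0 else 1
print(f"leader area              {leader}")
print("A lag fraction around 0.25-0.35 T (neither 0 nor 0.5) means the two")
print("identical areas settled into a leader/laggard state on their own.")
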