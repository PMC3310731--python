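"""Transfer entropy on a ground-truth surrogate pair.

Generates two coupled oscillator channels whose cycle amplitudes propagate
from leader to laggard with a known lag, quantizes them, and estimates TE
in both directions plus the causal unbalance U.  The forward TE exceeding
the backward one (U > 0) recovers the imposed direction.
"""

import numpy as np

from effconn import (SurrogateSpec, gen_lagged_oscillators, quantize,
                     transfer_entropy, unbalance, significance_test, BootstrapConfig)

spec = SurrogateSpec(seed=42, n_cycles=400)
t, leader, laggard, truth = gen_lagged_oscillators(spec)
tau = int(round(truth["lag_samples"]))

ql, qg = quantize(leader, 4), quantize(laggard, 4)
fwd = transfer_entropy(ql, qg, tau)
bwd = transfer_entropy(qg, ql, tau)
u = unbalance(fwd, bwd)
print(f"TE leader->laggard  {fwd.value:.3f} bits  (lag {tau} samples)")
print(f"TE laggard->leader  {bwd.value:.3f} bits")
print(f"causal unbalance U  {u.u:+.3f}   (positive = imposed direction recovered)")

summ = significance_test([leader, laggard], n_bins=4, tau=tau,
                         config=BootstrapConfig(n_joint=100, n_indep=100, seed=0))
for d, s in summ.items():
    print(f"direction {d}: median {s.median:.3f}, baseline upper whisker "
          f"{s.baseline_whisker_hi:.3f}, significant = {s.significant}")
print("Both directions carry dependence here (the laggard copies the leader's")
print("amplitudes within the same cycle); the sign of U identifies the driver.")
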