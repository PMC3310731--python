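# effconn

**Dynamic effective connectivity of oscillating neural circuit motifs.**

A fixed, fully symmetric anatomical motif of reciprocally coupled brain
areas can express many different *effective* connectivity patterns — the
directed graphs of statistically significant causal influence. `effconn`
implements the full analysis chain showing how this happens in two
complementary models (a delayed-inhibition mean-field rate model and sparse
networks of Wang–Buzsáki spiking neurons), why it happens (spontaneous
symmetry breaking of phase-locked gamma-band oscillations), how the active
pattern can be flipped by a single phase-timed pulse (phase-response
theory), and what it means for communication (spike-level information flows
only along the effectively connected direction).

The package is aimed at computational neuroscientists studying inter-areal
coordination, oscillatory dynamics, and directed-connectivity inference from
field-potential-like signals.

## The models and measures

Rate model — each area is one unit with delayed inhibition and delayed
cross-excitation,

    tau dnu_i/dt = -nu_i(t) + [ I0 - K nu_i(t-D) + sum_j K12 nu_j(t-D12) ]_+ ,

oscillating for strong `K` and locking out-of-phase across areas past a
pitchfork bifurcation in `K` (leader/laggard states).  Spiking model — each
area is a conductance-based E/I network in the sparsely synchronized gamma
regime (collective ~50 Hz rhythm, single neurons firing every ~6 cycles).

Directed influence between the per-area signals x, y is measured by
first-order transfer entropy at lag tau on n-bin quantized series,

    TE(x->y) = sum p(y_{t+tau}, y_t, x_t) log2 [ p(y_{t+tau}|y_t, x_t) / p(y_{t+tau}|y_t) ] ,

partialized on the third area for three-area motifs, validated against a
geometric (cycle-block) bootstrap: a direction counts as significant when
its jointly resampled TE distribution clears the independently resampled
baseline. Significant directions form the effective motif, classified as
unidirectional / leaky / mutual via the causal unbalance
U = (TE_xy - TE_yx)/(TE_xy + TE_yx). Spike-level transmission over a
synapse is quantified by per-cycle binary codes and normalized mutual
information MI/H.

## Worked example

```
$ python examples/rate_oscillations.py
mean oscillation period  T = 4.29 time units
cycles detected          233
inter-areal lag          +1.14 (0.27 T)
leader area              0
A lag fraction around 0.25-0.35 T (neither 0 nor 0.5) means the two
identical areas settled into a leader/laggard state on their own.
```

Two identical areas, symmetric wiring — yet one leads by about a quarter
cycle: the symmetry broke spontaneously. Running
`examples/effective_motif_census.py` then shows that transfer entropy is
significant **only** leader-to-laggard, and that across random initial
conditions exactly the two mirror-image unidirectional motifs appear.
`examples/switching_pulse.py` predicts from the phase-response curve the
narrow window of oscillation phases where a small pulse flips leadership,
and verifies one pulse inside (switches) and one outside (does not).
Other examples cover the transfer-entropy estimator on ground-truth
surrogates, the spiking network's sparse synchrony, and spike-train
information through a known channel.

A thin CLI mirrors the workflows (`effconn census`, `effconn switch`,
`effconn te`, `effconn info`, `effconn simulate-rate`, ...); see
`effconn --help`.

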