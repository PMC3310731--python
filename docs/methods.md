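# Methods

`effconn` studies how one fixed, fully symmetric structural motif of
reciprocally coupled oscillating neural areas generates *multiple* effective
connectivity motifs — directed graphs of statistically significant causal
influences — and how the active motif can be switched by phase-timed pulses
and gates spike-level information transfer. This note documents the models,
estimators, numerical choices, and the limits of what the shipped desk-scale
experiments demonstrate.

## Rate model

Each area is one mean-field unit with delayed local inhibition and delayed
long-range excitation:

    tau dnu_i/dt = -nu_i(t) + [ I0 - K nu_i(t-D) + sum_{j!=i} K12 nu_j(t-D12) ]_+

Time is dimensionless (unit leak time constant, exposed as `tau`). Delayed
inhibition makes an isolated unit oscillate once `K` is large enough at fixed
delay `D`; the oscillation is a relaxation cycle whose rectifier gate
(`I0 - K nu(t-D) > 0`) is open only during part of the cycle. That gate is the
communication-through-coherence mechanism in its purest form: input arriving
while the gate is closed has literally no effect.

Integration is fixed-step explicit Euler with linear interpolation in the
delay buffer, `dt <= D/50` by default and validated against a 10x-finer
reference in the tests (period agreement within 1%). Rates are rectified at
every step. Optional white noise on the background current uses
Euler–Maruyama scaling, so its strength is step-size independent.

### Regimes

The printed parameter values of the original figures are not available, so
the three dynamical regimes were reconstructed behaviorally by scanning the
cross-coupling `k_cross` (the scan is a shipped code path,
`effconn.config.discover_regimes`, classifying each grid point by
bifurcation-diagram branch multiplicity, per-area amplitude irregularity, and
leadership-exchange rate). The frozen two-area geometry is `I0=1, K=40, D=1,
D12=0.25`:

| regime  | k_cross | deterministic dynamics                          | expected family |
|---------|---------|--------------------------------------------------|-----------------|
| weak    | 2.0     | periodic, out-of-phase locked (lag ~0.27 T)      | unidirectional  |
| leaky   | 3.5     | laggard amplitudes fluctuate, stable leadership  | leaky           |
| strong  | 6.0     | symmetric irregularity, frequent leader exchange | mutual          |

Two further configurations are shipped: `switching` (`K=20, D12=0.5,
k12=0.1`), a weakly coupled bistable pair where phase-reduction theory is
quantitative, and `n3_weak` (`K=140, D12=0.1, k12=1.0`), the three-area
configuration whose out-of-phase states are *hierarchical* (phase offsets
0, ~0.16 T, ~0.32 T: source / middle / sink) rather than evenly splayed.
Strong inhibition and a short cross delay are what pushes the pairwise
preferred lag well below T/3; at moderate inhibition the three-area system
settles into an exact splay state (offsets T/3 apart), which is cyclically
symmetric and cannot exhibit a causal source or sink.

The rate model is deterministic; its strictly periodic states carry no
cycle-to-cycle fluctuations for transfer entropy to work with. The census
conditions therefore include weak background-current noise (amplitude 0.02
for two areas, 0.005 for three, chosen once: small enough that spontaneous
leadership switches stay rare — the three-area states wander between
hierarchy configurations at 0.02 — large enough that amplitude fluctuations
propagate measurably). This plays the role the finite-size stochasticity of
the spiking network plays in the companion model.

## Spiking network

Each area is a sparse random network of 400 excitatory and 100 inhibitory
Wang–Buzsáki single-compartment neurons (C=1 uF/cm2, gL=0.1, gNa=35, gK=9
mS/cm2, phi=5) — all cells share the interneuron parameter set, with
class-specific synaptic conductances — driven by independent Poisson input
(3 kHz per neuron onto an AMPA-like conductance of 0.006 mS/cm2). Synapses
are exponential conductances (AMPA-like, tau=2 ms, E=0 mV; GABA_A-like,
tau=6 ms, E=-75 mV) with transmission delays (1.5 ms local, 3–4 ms
cross-areal). Within an area, ordered pairs connect independently with
class probabilities ((E→E 0.05, E→I 0.4), (I→E 0.4, I→I 0.4)); across areas
only excitatory cells project, with probability `p_cross=0.05` to both
target types. Integration is exponential-Euler at 0.05 ms (conductance decay
exact, membrane update with the instantaneous conductance linearization);
spikes are upward crossings of -20 mV with a 2 ms refractory floor for event
recording. The "LFP" is the unweighted mean membrane potential per area at
0.5 ms resolution.

The default drive/inhibition balance (g_inh=0.05 mS/cm2, background 3 kHz)
was calibrated so the collective rhythm sits in the gamma band (~50 Hz)
while the mean single-neuron rate is about a fifth of it — the sparse
synchronization regime where neurons skip most cycles and fire at most once
per cycle. Two coupled areas lock out-of-phase (lag ~0.25–0.4 T) with one
area leading. At the shipped desk scale (500 cells/area; 1000/area in the
switching experiments) finite-size fluctuations occasionally flip
leadership spontaneously; dwell times grow quickly with network size
(roughly 15 cycles at 500/area, 40–90 at 1000/area for the 3 ms cross
delay). Production-scale counts are reachable through `AreaNetworkParams`.

Transmission lines (TLs) embed `n_source` one-to-one strengthened synapses
from excitatory source cells of one area onto a disjoint target
sub-population (half excitatory, half inhibitory) of the other, with
conductance multiplier `eta`. `tune_tl_multiplier` raises `eta` on a grid
until the inter-areal lag collapses toward in-phase and returns the last
value that leaves the out-of-phase locking intact.

## Phase reduction and response

The empiric phase grows linearly by 2*pi over each detected cycle (cycle
starts at upward mean-crossings), adapting elastically to cycle-length
fluctuations. Cycle detection estimates the dominant period by
autocorrelation first and then enforces half-period separation between
peaks and between crossings, which makes it robust to percent-level noise.

Two response descriptions are used:

* **Adjoint PRC (rate model).** The infinitesimal PRC of the single-unit
  limit cycle solves the adjoint variational equation of the delay system,
  `z'(t) = (1/tau)[z(t) + K gate(t+D) z(t+D)]`, integrated backward until
  periodic convergence. Normalization uses the delay-system bilinear form
  `z(t) nudot(t) + int_{-D}^{0} z B nudot` (constant on the cycle, set to
  2*pi/T); the naive pointwise product `z nudot` is *not* conserved for a
  DDE and silently misnormalizes. The measured small-pulse response agrees
  with `A * Z(phi)` to within 10% of the curve amplitude (tested).

* **Finite-pulse response (both models).** A pulse at phase `phi` of the
  ongoing cycle; the asymptotic shift is read from the cross-correlogram of
  perturbed vs unperturbed series over 50 cycles starting at the 10th cycle
  after the pulse, converted to phase with the autocorrelation-estimated
  period. For the noisy network model the pair of runs shares the seed
  (frozen background), and the number of trials controls the residual
  phase-diffusion noise.

The weak-coupling phase-difference velocity is assembled as
`G(dphi) = C(-dphi) - C(dphi)` with
`C(psi) = (k/2pi) int R(phi) gate(phi) w(phi + psi - theta_D) dphi`, where
`R` is the response (infinitesimal PRC times the coupling, or the measured
finite-pulse curve), `w` the (averaged) limit-cycle waveform and `theta_D`
the cross-delay as phase. For identical units `G` is odd, so 0 and pi are
always zeros; sweeping the local inhibition moves the system through a
pitchfork where anti-phase locking loses stability to a mirror pair of
out-of-phase lockings — reproduced by `find_lockings` (negative-slope zero
crossings, basins bounded by the adjacent unstable zeros) and matching the
directly simulated lag within 5% of a cycle.

## Switching control

In the bistable out-of-phase regime a pulse advancing the perturbed area's
phase by `Delta(phi, A)` kicks the phase difference toward the mirror
basin; `predict_intervals` marks the application phases for which the
kicked difference lands there. The rate-model experiments use an
instantaneous state kick `nu += A` (impulse approximation); the network
uses a rectangular current of one-twentieth period. Classification of the
settled motif discards 10 cycles and reads the lag sign; the deterministic
rate model reproduces the predicted windows with at most one boundary
grid-bin of disagreement and settles within ~10 cycles. Pulse strength is
calibrated as the smallest grid value giving a predicted window at least
5% of a cycle wide.

## Transfer entropy and significance

TE is plug-in, first Markov order, base 2, on equal-width-quantized signals
(each series over its own [min, max]); the partialized variant conditions on
the third area. `cond_lag` places the conditioning sample of the third
series at `z_{t+cond_lag}` (default 0); for the synthetic Markov chain
x -> z -> y, conditioning the mediator at the time it mediates
(`cond_lag = tau`) removes the indirect path exactly, while `cond_lag = 0`
cannot block influence that is routed through the mediator's *future*.
Under-sampling flags fire below 10 n^3 (10 n^4) transition tuples.

Significance uses the geometric bootstrap: blocks start at upward
mean-crossings and span a geometric number of cycles (mean 20), concatenated
to the original length; joint mode replays channel 0's block plan on all
channels, independent mode draws per channel. A direction is significant
when the joint replicas' lower Tukey whisker clears the independent
replicas' upper whisker and a two-sample rank test separates the
distributions (alpha = 0.05); otherwise a single baseline band is reported.
Default 500 + 500 replicas (reduced to 100–150 in the desk-scale censuses).

Epoch handling mirrors the locking dynamics: per-cycle leadership labels
(lag sign over a short window) define configurations; when labeling is
stable (label changes in at most 5% of cycles) the analysis keeps only the
dominant configuration with 5 cycles dropped after every change, splicing
the surviving whole cycles. When leadership exchanges frequently (the
mutual regime has no stable configuration) the whole record is analyzed —
conditioning on a leadership label there would manufacture asymmetry.

### Census working points

Absolute TE values depend on the bin count and the probing lag; the scan
(`te_scan`) is the robustness instrument, and the censuses classify at one
frozen working point per regime. For the two-area regimes the point is
n = 2 bins at a lag of ~0.6 T. The reason for that lag is a property of
clean quantized oscillations worth recording: at coarse quantization the
laggard-to-leader information has a narrow *null* near 0.6 T (and again one
period later) where the leader's own past screens the laggard's sample
exactly, while leader-to-laggard information stays flat and high. Because
the null is one sample wide at 0.1-time-unit sampling, the weak-regime
census places the lag within the window [0.55 T, 0.65 T] at the maximum of
the signed TE contrast of the measured leader -> laggard pair. The
three-area census probes at 0.2 T (the hierarchical step lag), n = 2, with
the partialized estimator. Defaults for general use remain n = 4 and a
quarter-period lag (`te_causality` defaults); the motif topology, not the
TE values, is the reproducible object.

## Spike-level information

Spike trains are digitized into per-cycle binary streams on each area's own
cycle grid (at most one spike per cycle in the sparse-synchrony regime;
excess spikes are clipped and counted). Directed pairs align symbols so
the effect follows the cause: same cycle index when the source area leads,
next target cycle when it lags. Entropy, MI and efficiency MI/H are
plug-in; debiasing re-estimates MI on random subsamples at data fractions
1, 1/2, 1/4, 1/8 and extrapolates the means quadratically in inverse data
fraction to zero (the BSC closed form is recovered within 2% at 1e5
pairs). Statistics run over up to 400 pairs per synapse set (reduced at
desk scale via configuration).

## Synthetic fixtures

`surrogates` provides ground-truth inputs: coupled oscillator channels with
AR(1) cycle amplitudes (coefficient 0.8) copied leader-to-laggard at a known
lag; Bernoulli streams through a binary symmetric channel with closed-form
H and MI; and the Markov triplet x -> z -> y with transition matrices
returned for exact TE computation. One honest caveat, verified in tests:
because the laggard channel copies the leader's amplitude *within the same
cycle*, both TE directions of the oscillator surrogate are genuinely
dependent; the recoverable ground truth there is the dominant direction
(sign of U, >= 95% of seeds), not one-sided significance. One-sided
significance is exercised on the rate model itself, whose rectifier gating
suppresses the backward path physically.

## What the desk-scale experiments do and do not show

Everything shipped runs on one CPU in minutes: censuses use 6000–9000 time
units and 100–300 bootstrap replicas; the spiking experiments use 500–1000
cells per area and tens of seconds of simulated time. These sizes reproduce
the structure of the full-scale analyses (family counts, switching windows,
ordering of TL efficiencies) but not their statistical sharpness: at
500 cells/area spontaneous leadership switches are only ~10-fold slower
than the rhythm, whereas in production-scale networks they are rare on the
scale of seconds. Passing tests therefore demonstrate the mechanisms and
the correctness of the estimators, not quantitative values for any real
cortical signal. Two spiking-network effects sit beyond the desk scale and
their end-to-end tests document that honestly by failing: the pulsed
switching histogram against the network's own measured locking functional
(the finite-pulse response has trial-to-trial spreads of order a radian at
these sizes, so the predicted windows are unreliable and spontaneous
leadership flips rival induced ones), and the *directional* selectivity of
transmission-line communication (TL efficiencies exceed control, but the
misaligned direction is not suppressed: the unfavorable-phase arrival
lands after the desk-scale inhibition has decayed, and conductances strong
enough to force spikes pull the areas in-phase first). The corresponding
rate-model experiments, where phase reduction is quantitative, are green. Real LFPs additionally violate the fixed-waveform,
noise-free-measurement assumptions of the surrogates, and TE analyses of
real data need the full robustness scan plus the bootstrap baseline rather
than any single working point.
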