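# Methods

`fragburst` models spontaneous network bursts (NBs) in cultured excitatory
neuronal networks recorded on multi-electrode arrays (MEAs), and the
fragmentation of those bursts — multiple peaks in the network firing rate
within a single burst — that characterizes many patient-derived cultures.
The package contains two network models, a set of synaptic-mechanism
extensions, a complete recording-to-features analysis pipeline, scripted
experiments, and a synthetic-recording generator with exact ground truth.

## The models

### Realistic network

100 Hodgkin–Huxley neurons with Na⁺/K⁺/leak channels plus a slow
afterhyperpolarizing (sAHP) potassium conductance, coupled by AMPA and
Mg²⁺-blocked NMDA receptor synapses with short-term depression (STD).
Heterogeneity enters through per-neuron constant drive I_ext ~
N(40, 25) pA, truncated-normal synaptic weights w ~ N(1, 0.4)·S (S a
global scale), and uniform axonal delays (1–5 ms).  Each neuron receives
Ornstein–Uhlenbeck current noise (σ = 11 pA, τ = 5 ms) standing in for
spontaneous EPSC-like fluctuations.

Membrane equation (units mV, ms, nS, pF, pA):

    C dV/dt = −I_Na − I_K − I_L − I_syn − I_sAHP − I_noise + I_ext

with classic squid-axon gating kinetics centred on a −65 mV rest.  The cell
is area-scaled to 2,000 µm² (C = 20 pF, g_Na = 2400 nS, g_K = 720 nS,
g_L = 6 nS): the published description of the prior model defers all
numeric values to a supplementary table that is not available, so membrane
and synaptic constants here are the package's own calibration (see
*Calibration* below).

The sAHP is a spike-triggered potassium conductance: g_sAHP increases by
δ = 2 nS per spike and decays exponentially with τ = 5 s.  It is the slow
negative feedback that terminates NBs and sets the inter-burst interval.

Synapses: each presynaptic spike, after its axonal delay, increments the
postsynaptic open-channel fractions s_AMPA (τ = 2 ms) and s_NMDA
(τ = 100 ms) by the synaptic weight times the plasticity amplitude factor.
Currents are conductance-based, g·s·(V − E_syn) with E_syn = 0 mV; the
NMDA term is additionally multiplied by the Jahr–Stevens magnesium block
B(V) = 1/(1 + [Mg]·e^(−0.062·V)/3.57) with [Mg] = 1 mM.

### Minimal network

100 *identical* exponential integrate-and-fire neurons (C = 100 pF,
g_L = 6 nS, E_L = −65 mV, Δ_T = 2 mV, V_T = −50 mV, hard threshold
−30 mV, reset −58 mV, 2 ms refractory), homogeneously connected
(p = 0.3, equal weights and delays) through a single generic exponential
receptor (τ = 5 ms).  It contains exactly the three ingredients needed for
bursting and fragmentation — recurrent excitation, sAHP adaptation
(δ = 0.4 nS, τ = 5 s), and STD — and nothing else.

### Short-term plasticity

The presynaptic resource fraction x follows the Tsodyks–Markram scheme.
Between spikes dx/dt = (1 − x)/τ_D (τ_D = 150 ms).  The package has three
presynaptic modes:

* **STD only** — on each spike the postsynaptic amplitude carries the
  factor x (pre-spike value) while U·x is consumed; U is the *strength* of
  depression (basal 0.006; the drug-emulation switch raises it to 0.035).
* **STP (depression + facilitation)** — a release probability u jumps by
  U(1 − u) *before* release, amplitude u·x, consumption u·x; between
  spikes u relaxes to U with τ_F.
* **Asynchronous release** — on top of STP, each terminal releases
  stochastically from the same vesicle pool: with x₀ = 0.02 resource per
  vesicle, the number of released vesicles per step is
  B(⌊x/x₀⌋, u_ar·dt), approximated (as in the original work) by a normal
  with matching mean and variance, rounded and clipped to [0, N].  The
  release rate u_ar rises toward its saturation U_ar on each spike
  (fractional jump 0.15) and decays with τ_ar = 250 ms, so release
  *outlasts* firing.  Note the approximation under-releases when
  N·u_ar·dt ≪ 1 (a sub-half-vesicle mean rounds to zero); tests therefore
  validate the mean both against the exact distribution of the
  approximation and against the binomial in a regime away from the clip
  boundary.

The u_ar update rule is not printed in the source material; the jump-toward-
saturation form above realizes the stated structure (separate saturation
and recovery constants; persistence after firing).

### Adaptation variants

The mAHP variant adds a second spike-triggered potassium conductance with
a 2–100 ms timescale (default 50 ms) and a conductance increment 60× the
sAHP's — the published magnitude at which a medium AHP can substitute for
STD as the fast activity brake.  It never replaces the sAHP (which is
still needed to terminate the NB); it replaces *STD* in the mAHP probe.

## Integration

One numba kernel integrates everything: exponential Euler for gating
variables, receptor/adaptation conductances and plasticity resources
(their between-spike dynamics are linear, so per-step decay factors are
exact), forward Euler for V, dt = 0.05 ms.  Spike delivery uses a circular
per-step arrival buffer with delays rounded to the grid.  Three
independent RNG streams (topology; membrane noise; asynchronous draws)
derive from one master seed, so toggling asynchronous release does not
perturb the noise realization; the noise/async streams are explicit
xorshift128+ generators whose state is carried bit-exactly across
scheduled-parameter segment boundaries.  Initial conditions: V at rest
plus 0.5 mV jitter, x = 1, u = U, g_AHP = 0; analyses discard a 5 s
burn-in.

Numerical caveat: with a fixed-step forward-Euler membrane update a
tonically firing neuron accumulates O(dt) period error per cycle, so
spike *phase* drifts linearly over long runs even though the firing period
converges first-order; convergence tests compare early spike times and the
period, not end-of-run phase.

## The analysis pipeline

Identical for simulated and experimental recordings, all thresholds
relative (the pipeline is exactly invariant under voltage rescaling):

1. 5th-order Butterworth band-pass 100–3,500 Hz, applied zero-phase
   (forward–backward) to preserve spike timing.
2. Spike detection at |V| > 4×RMS of the channel, 1 ms dead time.  RMS is
   taken over the full trace (the published description does not restrict
   it to a noise segment).
3. Network firing rate: spikes of all electrodes binned at 25 ms.
4. Gaussian smoothing, kernel sd = 2 bins (50 ms), unit-sum, reflective
   boundaries.  The kernel width is not printed in the source; 50 ms keeps
   the 100 ms-scale intra-burst oscillations (fragments) while suppressing
   bin noise.
5. NB detection: start when the smoothed rate holds ≥ max/4 for 50 ms
   (2 bins), extend to the max/100 crossings, stop when it holds < max/100
   for 50 ms; keep only NBs in which ≥ 30% of the active electrodes
   (mean rate > 0.02 Hz) fire; merge overlaps.  "Max" is the maximum of
   the smoothed rate over the analyzed segment.
6. Fragments: peaks of the smoothed rate inside each NB with height
   ≥ max/16 and topographic prominence ≥ max/10.
7. Features: NBR (NBs/min, all NBs), NBD (mean duration, s), CV_IBI
   (population-sd coefficient of variation of start-to-start intervals;
   undefined below 3 NBs), fragments/NB.  NBs clipped by the recording
   edges count for NBR but are excluded from NBD and fragment statistics.

## Calibration

No numeric parameter table for the realistic model is available, so the
defaults were calibrated once to the published phenomenology of *healthy*
cultures and then frozen: a quiescent baseline with sparse noise-driven
spikes; network-wide bursts ignited by noise fluctuations and terminated
by the sAHP; a basal burst rate of a few NBs per minute (the printed basal
acceptance band is 1.8–4.8 NBs/min) with one firing-rate peak per burst;
and basal STD weak (U = 0.006) so depression shapes nothing until it is
enhanced.  The burst rate is exponentially sensitive to the noise
amplitude σ (ignition is a rare-fluctuation event), which is the physical
reason the model — like the cultures — shows seed-to-seed variability in
NBR.

Raising U to 0.035 mid-run (the in-silico counterpart of bath-applying an
endocytosis blocker) shortens NBs and raises their rate in this
configuration; fragment counts stay at ≤ 2 per NB.  Both published
outcomes — two fragments, or a single fragment with very short NBs —
depend on the excitation/depression balance of the particular network;
this default configuration expresses the single-fragment branch, and the
minimal model expresses the two-fragment transition as U rises.

Mechanism probes apply *strong* settings of one mechanism each (presets in
`fragburst.experiments.PROBE_PRESETS`, every value config-overridable) on
top of a baseline with sufficient STD; their published parameter values
are likewise not printed, so the presets are chosen to sit well inside the
respective multi-fragment regimes.

## The synthetic-recording generator

`fragburst.fixtures` builds 12-channel, 10 kHz recordings from an explicit
plan: Gaussian background noise (10 µV), a biphasic 1 ms cosine-windowed
spike template (default 8× noise sd), and burst envelopes that are sums of
Gaussian sub-bumps driving per-electrode inhomogeneous-Poisson spiking
(thinning algorithm).  Ground truth (spike times, NB intervals, fragment
counts) is recorded exactly, which makes the generator the regression
oracle for the pipeline.  It emulates the *structure* of an MEA recording,
not its biophysics: spike waveforms are identical across units, noise is
white and stationary, and bursts are imposed rather than emergent — so
pipeline tests on fixtures validate detection logic and thresholds, not
the models.

## Scaled-down experiments

The published parameter screen used 120,000 simulations; its parameter
ranges are not printed.  `run_sweep` reproduces the design at configurable
scale: Latin-hypercube sampling (scipy `qmc`) over the nine screened
parameters (σ, g_Na, g_K, g_sAHP-increment δ, S, τ_sAHP, connection
probability, τ_D, U), default ranges ±50% around baseline, 200 points of
180 s by default (an hours-long background job; the test suite exercises
the machinery at a few points).  Acceptance bounds for basal activity
default to the printed NBR band plus configurable estimates for the other
three features (their printed values are figure whiskers unavailable
here).  Accepted configurations are re-simulated with U×1.5.

Problem sizes used by the shipped tests and the acceptance script — 3
network seeds × 3 simulated minutes for the basal burst rate; 2 seeds ×
(100 s + 100 s) for the drug-emulation protocol in the test suite (the
protocol object defaults to the full 5 min + 5 min); 100 s per mechanism
probe — are the package's default desk scale; all are configurable.

## Known limitations

* All parameter defaults are this package's calibration, not the original
  supplementary values; quantitative features other than those calibrated
  (e.g. absolute intra-burst firing rates) should not be read as
  predictions.
* Excitatory-only networks; no inhibition, no separate vesicle pools for
  synchronous vs asynchronous release, no distance-dependent connectivity,
  no extracellular-field model (virtual electrodes average somatic
  potential deviations and add white measurement noise).
* The normal approximation to binomial vesicle release biases the
  asynchronous release rate downward at very low rates (see above).
* Delays are rounded to the integration grid; scheduled parameter switches
  take effect at step boundaries.
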