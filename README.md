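# fragburst

Simulation and MEA analysis of **fragmented network bursts** in excitatory
neuronal cultures.

Cultured excitatory networks (e.g. hiPSC-derived neurons on multi-electrode
arrays) fire in *network bursts* (NBs): transient, network-wide surges of
spiking.  In many patient-derived cultures these bursts are *fragmented* —
the network firing rate oscillates inside a single burst, producing several
peaks ("fragments") instead of one.  `fragburst` provides the in-silico
machinery to study when and why fragments emerge:

* a **realistic network model** — 100 heterogeneous Hodgkin–Huxley neurons
  with AMPA + Mg²⁺-blocked NMDA synapses, slow afterhyperpolarization
  (sAHP), Tsodyks–Markram short-term depression (STD), membrane noise, and
  virtual electrodes sampled at 10 kHz;
* a **minimal model** — 100 identical exponential integrate-and-fire
  neurons with generic synapses, containing only recurrent excitation,
  sAHP and STD;
* **synaptic-mechanism extensions** — short-term facilitation (STF),
  stochastic asynchronous vesicle release from the shared pool, and a
  medium-timescale AHP;
* the full **MEA analysis pipeline** — 100–3,500 Hz band-pass, 4×RMS spike
  detection, 25 ms-binned network firing rate, Gaussian smoothing,
  two-threshold NB detection with an electrode-participation criterion,
  prominence-based fragment detection, and the summary features NBR
  (bursts/min), NBD (burst duration), CV_IBI and fragments/NB;
* **scripted experiments** — a mid-run STD-enhancement (drug-emulation)
  protocol, Latin-hypercube parameter screening, and single-mechanism
  probes;
* a **synthetic-recording generator** with exact ground truth for testing
  the pipeline.

## The core model

The presynaptic resource fraction `x_j` of neuron *j* obeys the
Tsodyks–Markram depression equation

    dx_j/dt = (1 − x_j)/τ_D − U·x_j·Σ_k δ(t − t_jk − Δ)

so each spike consumes a fraction `U` of the available resource and the
postsynaptic amplitude carries the factor `x_j`.  Bursts arise from the
interplay of recurrent excitation and the sAHP conductance (incremented on
every spike, decaying over seconds): excitation ignites a burst, the sAHP
terminates it.  When STD is strong enough to transiently lower the firing
*before* the sAHP has accumulated, the burst breaks into fragments — and
any mechanism that keeps excitation alive after firing stops (asynchronous
release, slow NMDA currents, facilitation) can multiply them.

## Worked example

```
$ python examples/simulate_and_analyze.py
network: 100 neurons, 3003 synapses, 12 virtual electrodes
simulated 65 s, 3076 spikes (0.47 Hz mean rate)
detected 3 network bursts in 60 s:
  NBR  = 3.00 NBs/min   (burst frequency)
  NBD  = 0.38 s         (mean burst duration)
  fragments/NB = 1.00  (healthy networks show ~1: one firing-rate peak per burst)
```

The basal network is quiet between bursts (~0.4 Hz mean rate), ignites a
network-wide burst every 15–30 s, and each burst has a single firing-rate
peak — the healthy-culture phenotype.  Other examples:

* `examples/minimal_model_transition.py` — raising the depression strength
  U in the minimal model fragments its bursts;
* `examples/dynasore_emulation.py` — switching U from 0.006 to 0.035
  mid-run shortens bursts and raises their rate (the in-silico analogue of
  an STD-enhancing drug);
* `examples/mechanism_probes.py` — asynchronous release, strong NMDA, STF
  and mAHP probes, each producing fragmented bursts;
* `examples/synthetic_fixture.py` — ground-truth recovery by the pipeline;
* `examples/parameter_sweep.py` — the scaled-down parameter screen
  (background job).

A thin CLI wraps the same functions: `fragburst simulate|analyze|synth|
dynasore|sweep|probe --help`.

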