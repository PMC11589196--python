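"""Parameter blocks for the network models, with YAML round-tripping.

Units are consistent throughout the package: membrane potential in mV,
time in ms (durations at the simulation-config level in s), conductance
in nS, capacitance in pF, current in pA.  With these units
``C dV/dt [pA] = nS * mV`` needs no conversion factors.

Every default below is overridable from a hierarchical YAML config file;
:func:`load_config` / :func:`dump_config` map between the two.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import yaml

__all__ = [
    "HHNeuronParams",
    "EIFNeuronParams",
    "AdaptationParams",
    "NoiseParams",
    "SynapseParams",
    "AsyncReleaseParams",
    "TopologyParams",
    "HeterogeneityParams",
    "ElectrodeLayout",
    "SimulationConfig",
    "NetworkConfig",
    "default_realistic_config",
    "default_minimal_config",
    "load_config",
    "dump_config",
    "replace_param",
]


@dataclass
class HHNeuronParams:
    """Hodgkin-Huxley neuron with Na/K/leak channels.

    Conductances in nS, capacitance pF, potentials mV.  Gating kinetics
    use the classic squid-axon rate functions shifted to a -65 mV resting
    potential; ``rate_scale`` multiplies all gating rates (a temperature-like
    factor).
    """

    C: float = 20.0  # pF (2,000 µm² at 1 µF/cm²)
    g_Na: float = 2400.0  # nS (120 mS/cm²)
    g_K: float = 720.0  # nS (36 mS/cm²)
    g_L: float = 6.0  # nS (0.3 mS/cm²)
    E_Na: float = 50.0  # mV
    E_K: float = -77.0  # mV
    E_L: float = -54.4  # mV
    rate_scale: float = 1.0  # multiplies all gating rates
    spike_threshold: float = 0.0  # mV, upward crossing counts as a spike
    spike_lockout: float = 2.0  # ms refractory for spike *detection*

    def validate(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be >= 0")
        if not (self.E_Na > self.E_L > self.E_K):
            raise ValueError("require E_Na > E_L > E_K")


@dataclass
class EIFNeuronParams:
    """Exponential integrate-and-fire neuron with hard reset."""

    C: float = 100.0  # pF
    g_L: float = 6.0  # nS
    E_L: float = -65.0  # mV
    Delta_T: float = 2.0  # mV, spike sharpness
    V_T: float = -50.0  # mV, soft threshold
    V_thres: float = -30.0  # mV, hard threshold (reset condition)
    V_reset: float = -58.0  # mV
    t_ref: float = 2.0  # ms absolute refractory after reset

    def validate(self) -> None:
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be > 0")
        if self.V_reset >= self.V_thres:
            raise ValueError("require V_reset < V_thres")
        if self.g_L <= 0:
            raise ValueError("g_L must be > 0")


@dataclass
class AdaptationParams:
    """Spike-triggered potassium adaptation conductance.

    The slow afterhyperpolarization (sAHP) accumulates ``delta`` nS per
    spike and decays with ``tau_sahp`` (seconds-scale); it terminates
    network bursts.  The medium AHP (mAHP) variant has the same form on a
    2-100 ms timescale with a conductance multiplier relative to sAHP and
    can substitute for short-term depression as the fast activity brake.
    """

    delta: float = 2.0  # nS added to g_sAHP per spike
    tau_sahp: float = 5000.0  # ms
    E_K_ahp: float = -77.0  # mV
    variant: str = "sahp"  # {"sahp", "mahp"}
    tau_mahp: float = 50.0  # ms (only used when variant == "mahp")
    mahp_multiplier: float = 60.0  # conductance step relative to sAHP delta

    def validate(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.variant not in ("sahp", "mahp"):
            raise ValueError("variant must be 'sahp' or 'mahp'")
        if self.tau_sahp <= self.tau_mahp:
            raise ValueError("require tau_sahp > tau_mahp")


@dataclass
class NoiseParams:
    """Ornstein-Uhlenbeck current noise into the membrane equation.

    Stationary standard deviation ``sigma`` (pA), correlation time
    ``tau_noise`` (ms).  Mimics spontaneous EPSC-like fluctuations.
    """

    sigma: float = 11.0  # pA
    tau_noise: float = 5.0  # ms

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau_noise <= 0:
            raise ValueError("tau_noise must be > 0")


@dataclass
class SynapseParams:
    """Receptor kinetics, weights and short-term plasticity.

    ``mechanism`` selects the presynaptic resource model:
    ``"std"``  - depression only (resource x, strength U, recovery tau_D);
    ``"stp"``  - depression + facilitation (release probability u,
                 facilitation recovery tau_F);
    ``"async"``- stp plus stochastic asynchronous release from the shared
                 vesicle pool;
    ``"none"`` - static synapses.

    ``receptors`` is ``"ampa+nmda"`` (fast AMPA plus slow, Mg-blocked NMDA)
    or ``"generic"`` (single exponential channel, minimal model).
    """

    g_syn_max: float = 1.2  # nS per unit weight (AMPA / generic channel)
    E_syn: float = 0.0  # mV
    tau_AMPA: float = 2.0  # ms
    tau_NMDA_decay: float = 100.0  # ms
    tau_syn: float = 5.0  # ms (generic receptor)
    nmda_ampa_ratio: float = 0.35  # g_NMDA = ratio * g_syn_max
    mg_conc: float = 1.0  # mM, Jahr-Stevens magnesium block
    w_mean: float = 1.0
    w_sd: float = 0.4
    S: float = 1.0  # global synaptic strength scale (multiplies weights)
    delay_min: float = 1.0  # ms, axonal delay lower bound
    delay_max: float = 5.0  # ms, upper bound
    U: float = 0.35  # STD strength (release fraction per spike)
    tau_D: float = 150.0  # ms, depression recovery
    tau_F: float = 750.0  # ms, facilitation recovery
    mechanism: str = "std"  # {"std", "stp", "async", "none"}
    receptors: str = "ampa+nmda"  # {"ampa+nmda", "generic"}

    def validate(self) -> None:
        if not (0 < self.U <= 1):
            raise ValueError("require 0 < U <= 1")
        if self.tau_D <= 0 or self.tau_F <= 0:
            raise ValueError("tau_D, tau_F must be > 0")
        if self.delay_min < 0 or self.delay_max < self.delay_min:
            raise ValueError("require 0 <= delay_min <= delay_max")
        if self.mechanism not in ("std", "stp", "async", "none"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.receptors not in ("ampa+nmda", "generic"):
            raise ValueError(f"unknown receptor set {self.receptors!r}")


@dataclass
class AsyncReleaseParams:
    """Stochastic asynchronous release competing for the shared pool x.

    ``u_ar`` (1/ms) rises toward the saturation ``U_ar`` on presynaptic
    spikes (fractional jump ``jump``) and decays to zero with ``tau_ar``;
    each vesicle (resource quantum ``x0``) releases with probability
    ``u_ar * dt`` per step, drawn from a normal approximation to the
    binomial clipped at its support.
    """

    U_ar: float = 0.02  # 1/ms, saturation of the asynchronous release rate
    U_sr: float = 0.35  # synchronous release saturation (alias of stp U usage)
    tau_ar: float = 250.0  # ms, asynchronous recovery (persists after firing)
    tau_sr: float = 50.0  # ms, synchronous sensor recovery
    jump: float = 0.15  # fractional step of u_ar toward U_ar per spike
    x0: float = 0.02  # neurotransmitter per vesicle (resource fraction)

    def validate(self) -> None:
        if not (0 < self.x0 <= 1):
            raise ValueError("require 0 < x0 <= 1")
        if not (0 <= self.U_ar <= 1):
            raise ValueError("require 0 <= U_ar <= 1")
        if self.tau_ar <= 0 or self.tau_sr <= 0:
            raise ValueError("time constants must be > 0")


@dataclass
class TopologyParams:
    n_neurons: int = 100
    connection_prob: float = 0.3
    culture_size: float = 1200.0  # µm, square side (4 electrode pitches)

    def validate(self) -> None:
        if not (0 <= self.connection_prob <= 1):
            raise ValueError("connection_prob must be in [0, 1]")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")


@dataclass
class HeterogeneityParams:
    """Per-neuron variability; ``homogeneous=True`` gives the minimal model
    (identical neurons and synapses, constant delays)."""

    I_ext_mean: float = 40.0  # pA constant external drive
    I_ext_sd: float = 25.0  # pA across neurons
    homogeneous: bool = False

    def validate(self) -> None:
        pass


@dataclass
class ElectrodeLayout:
    """12-electrode grid (3 x 4), 300 µm pitch, 80 µm diameter."""

    n_rows: int = 3
    n_cols: int = 4
    pitch: float = 300.0  # µm
    diameter: float = 80.0  # µm
    capture_radius: float = 150.0  # µm, neurons within this radius recorded
    noise_sd: float = 10.0  # µV measurement noise on each channel

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def validate(self) -> None:
        if self.capture_radius < 0:
            raise ValueError("capture_radius must be >= 0")


@dataclass
class ScheduleEvent:
    """Change one scalar parameter mid-run: (time_s, 'block.field', value)."""

    time_s: float
    path: str
    value: float


@dataclass
class SimulationConfig:
    dt: float = 0.05  # ms
    duration: float = 60.0  # s
    burn_in: float = 5.0  # s discarded before analysis
    seed: int = 0
    record_fs: float = 10000.0  # Hz, virtual-electrode sampling rate
    state_stride_ms: float = 1.0  # decimation of state traces
    schedule: list = field(default_factory=list)  # list of ScheduleEvent

    def validate(self, neuron_kind: str) -> None:
        if neuron_kind == "hh" and self.dt > 0.1:
            raise ValueError("HH integration requires dt <= 0.1 ms")
        stride = 1000.0 / self.record_fs / self.dt
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError("dt must divide the recording sample interval")
        for ev in self.schedule:
            t = ev.time_s if isinstance(ev, ScheduleEvent) else ev[0]
            if not (0 <= t <= self.duration):
                raise ValueError("schedule times must lie within duration")


@dataclass
class NetworkConfig:
    """Full description of one model: neuron kind + all parameter blocks."""

    neuron_kind: str = "hh"  # {"hh", "eif"}
    hh: HHNeuronParams = field(default_factory=HHNeuronParams)
    eif: EIFNeuronParams = field(default_factory=EIFNeuronParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    async_release: AsyncReleaseParams = field(default_factory=AsyncReleaseParams)
    topology: TopologyParams = field(default_factory=TopologyParams)
    heterogeneity: HeterogeneityParams = field(default_factory=HeterogeneityParams)
    electrodes: ElectrodeLayout = field(default_factory=ElectrodeLayout)

    def validate(self) -> None:
        if self.neuron_kind not in ("hh", "eif"):
            raise ValueError(f"unknown neuron kind {self.neuron_kind!r}")
        for block in (
            self.hh,
            self.eif,
            self.adaptation,
            self.noise,
            self.synapse,
            self.async_release,
            self.topology,
            self.heterogeneity,
            self.electrodes,
        ):
            block.validate()


def default_realistic_config() -> NetworkConfig:
    """100 heterogeneous HH neurons, AMPA+NMDA synapses, sAHP, weak basal STD.

    Defaults are calibrated so that the basal network, analyzed by the MEA
    pipeline, bursts at a few NBs per minute with non-fragmented bursts.
    """
    cfg = NetworkConfig(neuron_kind="hh")
    cfg.synapse.mechanism = "std"
    cfg.synapse.receptors = "ampa+nmda"
    cfg.synapse.U = 0.006  # basal STD strength
    return cfg


def default_minimal_config() -> NetworkConfig:
    """100 identical EIF neurons, generic synapses, sAHP, STD."""
    cfg = NetworkConfig(neuron_kind="eif")
    cfg.heterogeneity = HeterogeneityParams(
        I_ext_mean=0.0, I_ext_sd=0.0, homogeneous=True
    )
    cfg.synapse = SynapseParams(
        g_syn_max=1.5,
        tau_syn=5.0,
        w_mean=1.0,
        w_sd=0.0,
        delay_min=1.5,
        delay_max=1.5,
        U=0.1,
        tau_D=150.0,
        mechanism="std",
        receptors="generic",
    )
    cfg.noise = NoiseParams(sigma=120.0, tau_noise=5.0)
    cfg.adaptation = AdaptationParams(delta=0.4, tau_sahp=5000.0)
    return cfg


# ---------------------------------------------------------------------------
# YAML config round-trip

_BLOCKS = {
    "hh": HHNeuronParams,
    "eif": EIFNeuronParams,
    "adaptation": AdaptationParams,
    "noise": NoiseParams,
    "synapse": SynapseParams,
    "async_release": AsyncReleaseParams,
    "topology": TopologyParams,
    "heterogeneity": HeterogeneityParams,
    "electrodes": ElectrodeLayout,
}


def load_config(path) -> NetworkConfig:
    """Read a hierarchical YAML config into a :class:`NetworkConfig`.

    Unknown keys raise; missing keys keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = NetworkConfig()
    if "neuron_kind" in raw:
        cfg.neuron_kind = raw.pop("neuron_kind")
    for name, cls in _BLOCKS.items():
        block_raw = raw.pop(name, None)
        if block_raw is None:
            continue
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block_raw) - valid
        if unknown:
            raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
        setattr(cfg, name, cls(**block_raw))
    if raw:
        raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
    cfg.validate()
    return cfg


def dump_config(cfg: NetworkConfig, path) -> None:
    doc = {"neuron_kind": cfg.neuron_kind}
    for name in _BLOCKS:
        doc[name] = dataclasses.asdict(getattr(cfg, name))
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def replace_param(cfg: NetworkConfig, path: str, value) -> NetworkConfig:
    """Return a copy of ``cfg`` with the dotted ``path`` (block.field) replaced.

    Raises ``KeyError`` for unknown paths — the contract behind scheduled
    parameter switches.
    """
    parts = path.split(".")
    if len(parts) == 1 and parts[0] == "neuron_kind":
        return dataclasses.replace(cfg, neuron_kind=value)
    if len(parts) != 2 or parts[0] not in _BLOCKS:
        raise KeyError(f"unknown parameter path {path!r}")
    block_name, field_name = parts
    block = getattr(cfg, block_name)
    if field_name not in {f.name for f in dataclasses.fields(block)}:
        raise KeyError(f"unknown parameter path {path!r}")
    new_block = dataclasses.replace(block, **{field_name: value})
    return dataclasses.replace(cfg, **{block_name: new_block})
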