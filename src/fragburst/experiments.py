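"""Scripted in-silico experiments.

* :func:`run_dynasore` — mid-run enhancement of short-term depression
  (U 0.006 -> 0.035) with pre/post feature comparison across network seeds,
  the in-silico counterpart of bath-applying the endocytosis blocker.
* :func:`run_sweep` — Latin-hypercube screen over the nine most influential
  model parameters; configurations whose basal features fall in the
  experimental acceptance ranges are re-simulated with U raised by 50%.
* :func:`run_probe` — single-mechanism probes (asynchronous release, NMDA,
  facilitation, mAHP-for-STD substitution) on top of a named baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import SimulationResult, run_simulation
from .mea import AnalysisConfig, FeatureTable, analyze_recording
from .network import build_network
from .params import (
    NetworkConfig,
    ScheduleEvent,
    SimulationConfig,
    default_realistic_config,
    replace_param,
)

__all__ = [
    "DynasoreProtocol",
    "DynasoreResult",
    "run_dynasore",
    "SweepConfig",
    "run_sweep",
    "MechanismProbe",
    "ProbeResult",
    "probe_config",
    "run_probe",
]


# ---------------------------------------------------------------------------
# Dynasore emulation


@dataclass
class DynasoreProtocol:
    """Simulate ``pre_duration`` s at basal STD strength, switch U to the
    enhanced value, continue ``post_duration`` s; analyze both phases."""

    pre_duration: float = 300.0  # s
    post_duration: float = 300.0  # s
    U_basal: float = 0.006
    U_dynasore: float = 0.035
    n_network_seeds: int = 3
    burn_in: float = 5.0  # s excluded at the start of the pre phase
    settle: float = 10.0  # s excluded after the switch

    def validate(self) -> None:
        if self.U_dynasore <= self.U_basal:
            raise ValueError("require U_dynasore > U_basal")


@dataclass
class DynasoreResult:
    pre_features: List[FeatureTable]
    post_features: List[FeatureTable]
    post_fragment_counts: List[np.ndarray]  # per seed, per-NB counts
    excluded_seeds: List[int]  # non-bursting in the pre phase

    def deltas(self) -> pd.DataFrame:
        """Per-seed post-minus-pre differences of the four features."""
        rows = []
        for pre, post in zip(self.pre_features, self.post_features):
            rows.append(
                {
                    "d_fragments_per_nb": post.fragments_per_nb - pre.fragments_per_nb,
                    "d_nbr": post.nbr - pre.nbr,
                    "d_nbd": post.nbd - pre.nbd,
                    "d_cv_ibi": post.cv_ibi - pre.cv_ibi,
                }
            )
        return pd.DataFrame(rows)


def run_dynasore(protocol: DynasoreProtocol,
                 base_config: Optional[NetworkConfig] = None,
                 seed: int = 0, dt: float = 0.05,
                 analysis: Optional[AnalysisConfig] = None) -> DynasoreResult:
    """Run the STD-enhancement protocol across network seeds.

    Each seed builds a fresh network at ``U_basal``, simulates through the
    scheduled switch to ``U_dynasore``, and analyzes the pre phase
    ([burn_in, switch)) and post phase ([switch+settle, end]) separately.
    Seeds with no NBs in the pre phase are excluded (the in-silico analogue
    of non-bursting-well exclusion).
    """
    protocol.validate()
    analysis = analysis or AnalysisConfig()
    cfg = base_config or default_realistic_config()
    cfg = replace_param(cfg, "synapse.U", protocol.U_basal)

    pre_feats, post_feats, frag_counts, excluded = [], [], [], []
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             ss.spawn(protocol.n_network_seeds)]
    for net_seed in seeds:
        model = build_network(cfg, net_seed)
        sim = SimulationConfig(
            dt=dt,
            duration=protocol.pre_duration + protocol.post_duration,
            seed=net_seed,
            schedule=[ScheduleEvent(protocol.pre_duration, "synapse.U",
                                    protocol.U_dynasore)],
        )
        result = run_simulation(model, sim)
        pre_rec = result.recording.slice_time(protocol.burn_in,
                                              protocol.pre_duration)
        post_rec = result.recording.slice_time(
            protocol.pre_duration + protocol.settle, sim.duration
        )
        _ann_pre, f_pre = analyze_recording(pre_rec, analysis)
        if f_pre.n_nbs == 0:
            excluded.append(net_seed)
            continue
        ann_post, f_post = analyze_recording(post_rec, analysis)
        pre_feats.append(f_pre)
        post_feats.append(f_post)
        frag_counts.append(ann_post.fragment_counts)
    return DynasoreResult(pre_feats, post_feats, frag_counts, excluded)


# ---------------------------------------------------------------------------
# Parameter sweep


#: the nine screened parameters, as dotted config paths
SWEEP_PARAMETERS = (
    "noise.sigma",
    "hh.g_Na",
    "hh.g_K",
    "adaptation.delta",  # sAHP increment per spike (the screened delta)
    "synapse.S",
    "adaptation.tau_sahp",
    "topology.connection_prob",
    "synapse.tau_D",
    "synapse.U",
)


def _default_ranges(cfg: NetworkConfig) -> Dict[str, Tuple[float, float]]:
    """±50% around the baseline value of each screened parameter.

    Exception: U spans the basal-to-enhanced depression region (0.003-0.05,
    bracketing the drug-emulation values) — ±50% around the basal 0.006
    would make the U-multiplier follow-up a no-op.
    """
    out = {}
    for path in SWEEP_PARAMETERS:
        block, fieldname = path.split(".")
        v = getattr(getattr(cfg, block), fieldname)
        lo, hi = 0.5 * v, 1.5 * v
        if path == "topology.connection_prob":
            hi = min(hi, 1.0)
        if path == "synapse.U":
            lo, hi = min(lo, 0.003), max(hi, 0.05)
        out[path] = (lo, hi)
    return out


@dataclass
class SweepConfig:
    """Scaled-down screening sweep.

    ``acceptance`` bounds mirror the basal in-vitro feature ranges; only
    the NB-rate band (1.8-4.8 NBs/min) is a printed value — the others are
    configurable estimates of the control-condition spread.
    """

    n_points: int = 200
    sim_duration: float = 180.0  # s per point
    u_multiplier: float = 1.5
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    acceptance: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "nbr": (1.8, 4.8),
            "fragments_per_nb": (0.0, 1.5),
            "nbd": (0.1, 5.0),
            "cv_ibi": (0.0, 1.0),
        }
    )
    dt: float = 0.05
    burn_in: float = 5.0


def _features_accepted(f: FeatureTable, acceptance) -> bool:
    vals = {
        "nbr": f.nbr,
        "fragments_per_nb": f.fragments_per_nb,
        "nbd": f.nbd,
        "cv_ibi": f.cv_ibi,
    }
    for key, (lo, hi) in acceptance.items():
        v = vals[key]
        if not np.isfinite(v) or v < lo or v > hi:
            return False
    return True


def _simulate_features(cfg: NetworkConfig, seed: int, duration: float,
                       dt: float, burn_in: float,
                       analysis: AnalysisConfig) -> FeatureTable:
    model = build_network(cfg, seed)
    sim = SimulationConfig(dt=dt, duration=duration, seed=seed)
    result = run_simulation(model, sim)
    rec = result.recording.slice_time(burn_in, duration)
    _ann, feats = analyze_recording(rec, analysis)
    return feats


def run_sweep(sweep: SweepConfig, base_config: Optional[NetworkConfig] = None,
              seed: int = 0, analysis: Optional[AnalysisConfig] = None,
              progress: bool = False) -> dict:
    """Latin-hypercube screen + STD-enhancement follow-up.

    Deterministic in (sweep, seed): the sample and all per-point simulation
    seeds derive from ``seed``.  Individual simulation failures are counted,
    not raised.  Returns a report dict with the per-point table and summary
    fractions (accepted, gained fragments, >2 fragments, feature-change
    directions among accepted points).
    """
    analysis = analysis or AnalysisConfig()
    cfg = base_config or default_realistic_config()
    ranges = dict(sweep.ranges) or _default_ranges(cfg)
    paths = list(ranges)
    lo = np.array([ranges[p][0] for p in paths])
    hi = np.array([ranges[p][1] for p in paths])

    sampler = qmc.LatinHypercube(d=len(paths), seed=seed)
    unit = sampler.random(sweep.n_points)
    points = qmc.scale(unit, lo, hi)
    point_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(sweep.n_points)
    ]

    rows = []
    n_failed = 0
    for k in range(sweep.n_points):
        c = cfg
        for p, v in zip(paths, points[k]):
            c = replace_param(c, p, float(v))
        row = {p: points[k][i] for i, p in enumerate(paths)}
        row["point"] = k
        try:
            base_f = _simulate_features(
                c, point_seeds[k], sweep.sim_duration, sweep.dt,
                sweep.burn_in, analysis,
            )
        except (FloatingPointError, RuntimeError):
            n_failed += 1
            row["status"] = "failed"
            rows.append(row)
            continue
        row.update(
            base_nbr=base_f.nbr, base_nbd=base_f.nbd,
            base_cv=base_f.cv_ibi, base_frag=base_f.fragments_per_nb,
        )
        accepted = _features_accepted(base_f, sweep.acceptance)
        row["accepted"] = accepted
        row["status"] = "ok"
        if accepted:
            c2 = replace_param(
                c, "synapse.U", min(1.0, c.synapse.U * sweep.u_multiplier)
            )
            try:
                post_f = _simulate_features(
                    c2, point_seeds[k], sweep.sim_duration, sweep.dt,
                    sweep.burn_in, analysis,
                )
                row.update(
                    post_nbr=post_f.nbr, post_nbd=post_f.nbd,
                    post_cv=post_f.cv_ibi, post_frag=post_f.fragments_per_nb,
                )
            except (FloatingPointError, RuntimeError):
                n_failed += 1
                row["status"] = "post_failed"
        rows.append(row)
        if progress:
            print(f"[sweep] point {k + 1}/{sweep.n_points} "
                  f"accepted={row.get('accepted')}")

    table = pd.DataFrame(rows)
    report = {"table": table, "n_points": sweep.n_points, "n_failed": n_failed}
    acc = table[table.get("accepted", pd.Series(dtype=bool)) == True]  # noqa: E712
    acc = acc[acc["status"] == "ok"] if "status" in acc else acc
    report["n_accepted"] = int(len(acc))
    report["fraction_accepted"] = len(acc) / max(1, sweep.n_points)
    if len(acc) and "post_frag" in acc:
        ok = acc.dropna(subset=["post_frag"])
        report["fraction_gained_fragments"] = float(
            np.mean(ok["post_frag"] > ok["base_frag"])
        )
        report["fraction_more_than_two_fragments"] = float(
            np.mean(ok["post_frag"] > 2.0)
        )
        report["fraction_nbr_up"] = float(np.mean(ok["post_nbr"] > ok["base_nbr"]))
        report["fraction_nbd_down"] = float(np.mean(ok["post_nbd"] < ok["base_nbd"]))
        report["fraction_cv_up"] = float(np.mean(ok["post_cv"] > ok["base_cv"]))
    return report


# ---------------------------------------------------------------------------
# Mechanism probes


@dataclass
class MechanismProbe:
    """One mechanism toggled against a baseline with sufficient STD.

    ``mechanism`` in {"async", "nmda", "stf", "mahp"}; ``overrides`` maps
    dotted parameter paths to values and defines the entire diff from the
    baseline config.
    """

    mechanism: str
    overrides: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mechanism not in ("async", "nmda", "stf", "mahp"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


#: strong-setting presets for each probe (relative to the realistic baseline)
PROBE_PRESETS: Dict[str, Dict[str, float]] = {
    # stochastic release persisting after firing; rides on the STP synapse
    "async": {
        "synapse.mechanism": "async",
        "synapse.U": 0.2,
        "async_release.U_ar": 0.004,
        "adaptation.delta": 0.35,
    },
    # slow Mg-blocked current reviving fragments; STD enhanced, no async
    "nmda": {
        "synapse.mechanism": "std",
        "synapse.U": 0.12,
        "synapse.nmda_ampa_ratio": 2.5,
        "adaptation.delta": 0.2,
    },
    # facilitation keeps release probability elevated after firing
    "stf": {
        "synapse.mechanism": "stp",
        "synapse.U": 0.06,
        "synapse.tau_F": 1500.0,
        "adaptation.delta": 0.35,
    },
    # medium AHP substituting for STD as the fast activity brake
    "mahp": {
        "synapse.mechanism": "none",
        "adaptation.variant": "mahp",
        "adaptation.delta": 0.2,
    },
}


def probe_config(base_config: NetworkConfig, probe: MechanismProbe
                 ) -> NetworkConfig:
    """Apply a probe's preset plus explicit overrides to the baseline."""
    probe.validate()
    cfg = base_config
    merged = dict(PROBE_PRESETS[probe.mechanism])
    merged.update(probe.overrides)
    for path, value in merged.items():
        cfg = replace_param(cfg, path, value)
    return cfg


@dataclass
class ProbeResult:
    features: FeatureTable
    fragment_counts: np.ndarray  # per NB
    state_traces: pd.DataFrame  # decimated x, u, u_ar, g_ahp, I_syn means
    result: SimulationResult


def run_probe(probe: MechanismProbe,
              base_config: Optional[NetworkConfig] = None,
              seed: int = 0, duration: float = 120.0, dt: float = 0.05,
              burn_in: float = 5.0,
              analysis: Optional[AnalysisConfig] = None) -> ProbeResult:
    """Simulate one mechanism probe and analyze it.

    Returns the feature table, the per-NB fragment counts, and the
    decimated state traces (resource x, release probabilities, adaptation
    conductances, synaptic current) for mechanism inspection.
    """
    analysis = analysis or AnalysisConfig()
    cfg = probe_config(base_config or default_realistic_config(), probe)
    model = build_network(cfg, seed)
    sim = SimulationConfig(dt=dt, duration=duration, seed=seed)
    result = run_simulation(model, sim)
    rec = result.recording.slice_time(burn_in, duration)
    ann, feats = analyze_recording(rec, analysis)
    return ProbeResult(
        features=feats,
        fragment_counts=ann.fragment_counts,
        state_traces=result.state_traces,
        result=result,
    )
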