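"""The no-fragment -> fragment transition in the minimal EIF model.

The minimal network (100 identical exponential integrate-and-fire neurons,
generic synapses, sAHP, short-term depression) bursts through the
excitation/adaptation interplay.  Raising the depression strength U past a
threshold makes the depression fast and deep enough to transiently lower
firing inside a burst: the burst breaks into fragments.
"""

from fragburst import (
    SimulationConfig,
    analyze_recording,
    build_network,
    default_minimal_config,
    replace_param,
    run_simulation,
)

for U in (0.1, 0.5):
    cfg = replace_param(default_minimal_config(), "synapse.U", U)
    model = build_network(cfg, seed=1)
    res = run_simulation(model, SimulationConfig(duration=125.0, seed=1))
    ann, feats = analyze_recording(res.recording.slice_time(5.0, 125.0))
    fc = ann.fragment_counts
    print(f"U={U}: {feats.n_nbs} NBs, {feats.fragments_per_nb:.2f} fragments/NB "
          f"(max {fc.max() if fc.size else 0}) — "
          + ("plain bursts" if U < 0.3 else "fragmented bursts"))
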