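"""NBS baseline on the same cohort, extent vs intensity variants.

The hard component-defining threshold makes NBS-extent blind to strong
single-edge effects (a one-edge component can never beat the null
maximum extent), while NBS-intensity detects them through their
statistic excess.
"""

from tfnbs import ScenarioConfig, nbs_inference, simulate_scenario

config = ScenarioConfig(scenario="mixed_cnr", topology="tree")
mask, cohort = simulate_scenario(config, seed=7)
single_edge = mask.components[3]  # one edge, CNR = 1
a, b = single_edge.edges[0]
print(f"planted single edge ({a}, {b}) with CNR {single_edge.cnr}")

for variant in ("extent", "intensity"):
    for threshold in (8.5, 12.0):
        res = nbs_inference(cohort, threshold, variant=variant,
                            n_perm=500, alpha=0.05, seed=7)
        n_sig = len(res.significant_components)
        found = bool(res.significant_edges[a, b])
        print(f"NBS-{variant:9s} F>{threshold:4.1f}: "
              f"{len(res.components)} components, {n_sig} significant, "
              f"single-edge effect detected: {found}")
# Typical output: intensity finds the single edge at every threshold,
# extent never does - matching the known blind spot of extent-based NBS.
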