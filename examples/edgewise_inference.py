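"""Edge-wise inference on one simulated cohort.

Plants the reference five-component effect pattern (32 edges, mixed
CNR) in a two-group cohort, runs the threshold-free enhancement with
E=0.5, H=3.0 and 1,000 permutations, and reports which edges survive
family-wise correction at alpha = .05.
"""

import numpy as np

from tfnbs import ScenarioConfig, TfnbsParams, simulate_scenario, tfnbs_inference

config = ScenarioConfig(scenario="mixed_cnr", topology="tree", n_per_group=100)
mask, cohort = simulate_scenario(config, seed=7)
print(f"cohort: {cohort.n_subjects} subjects, {cohort.node_count} nodes, "
      f"{mask.edge_count} planted edges in {len(mask.components)} components")

result = tfnbs_inference(cohort, TfnbsParams(E=0.5, H=3.0), n_perm=1000, seed=7)
sig = result.fwe.significant_edges(alpha=0.05)
hits = int(np.triu(sig, 1).sum())
true_hits = int(np.triu(sig * mask.T, 1).sum())
print(f"ladder interval dh = {result.scores.dh_used:.3f} "
      f"(statistic maximum / 100)")
print(f"{hits} edges significant at corrected p <= .05; "
      f"{true_hits} of them are planted effects, {hits - true_hits} false positives")
for idx, comp in enumerate(mask.components, 1):
    found = sum(1 for a, b in comp.edges if sig[a, b])
    print(f"  component {idx}: CNR {comp.cnr:.2f}, "
          f"{found}/{comp.extent} edges recovered")
# Strong or well-clustered effects (CNR >= 0.75, and the CNR=1 single edge)
# are recovered almost completely; weak isolated effects (CNR 0.5) are often
# missed - the expected behaviour of the enhancement.
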