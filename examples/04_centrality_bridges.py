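"""Show that multisensitive cells occupy high-betweenness bridge positions.

The generator places cells sensitive to both agonists at the interface
between the two sensitivity communities; betweenness centrality against a
position-randomization null reveals that strategic placement.
"""

import numpy as np

from vasonet import (
    SimulationConfig,
    assign_sensitivities,
    build_tissue_graph,
    centrality_permutation,
    centrality_table,
    generate_tessellation,
    group_centrality,
)

config = SimulationConfig(n_cells=200, rng_seed=4)
root = np.random.default_rng(4)
streams = root.spawn(2)
mask, _ = generate_tessellation(config, streams[0])
tissue = build_tissue_graph(mask)
truth = assign_sensitivities(tissue, config, streams[1])

interior = set(tissue.interior)
table = centrality_table(tissue)
ach = truth.sensitive_to("ACh") & interior
bk = truth.sensitive_to("BK") & interior
obs = group_centrality(table, ach, bk)
print(obs[["n", "betweenness", "global_eigen", "local_influence"]].round(3))

nulls = centrality_permutation(
    tissue, {"multisensitive": len(ach & bk)}, n_perm=100, seed=5,
    table=table, observed=obs,
)
pn = nulls[("multisensitive", "betweenness")]
print(f"\nmultisensitive betweenness: observed {pn.observed:.0f} "
      f"vs null {pn.null_mean:.0f} (percentile {pn.percentile:.0f})")

# The multisensitive group's mean betweenness sits near the null's 100th
# percentile: cells responding to both agonists lie on the shortest paths
# linking the two unisensitive communities - communication bridges.
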