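# vasonet

Network analysis of agonist-evoked Ca²⁺ signaling in vascular endothelium.

Endothelial cells lining arteries and veins respond to agonists such as
acetylcholine (ACh) and bradykinin with discrete Ca²⁺ transients, and the
*spatial organization* of the responding cells — who responds, who their
neighbors are, who bridges between responder communities — carries as much
information as the transients themselves. `vasonet` turns per-cell
fluorescence traces (F/F₀) plus a labeled cell mask into that network-level
description:

* **Event detection** — Savitzky–Golay smoothing (21 pt, 3rd order),
  automatic 10-s lowest-activity baseline, 5× baseline-SD threshold, and an
  exponentially modified Gaussian (EMG) fit per transient giving amplitude,
  rise time, fall time and FDHM.
* **Tissue graph** — cells become nodes; neighbors are found by expanding
  cell boundaries until they touch; field-of-view edge cells are flagged by
  an alpha shape and excluded.
* **Responder communities** — the top 20% of cells by event frequency,
  their connected communities, degree of clustering and clustering
  coefficient, against a 100-fold activity-randomization null.
* **Centrality** — betweenness, global eigenvector centrality, and local
  influence from the eigenvectors up to the largest eigengap (L2 row
  norms), with group-vs-null enrichment for unisensitive and multisensitive
  cells.
* **Neighbor influence** — case–control estimate of P(event | k active
  neighbors) in windows of 3× the median FDHM, cluster vs non-cluster
  neighbors, against a temporal permutation null that shuffles event times
  while preserving per-cell counts.
* **Cross-correlation** — lagged, segmented, demeaned-normalized pairwise
  coefficients in [0, 1], summarized per node by the 75th percentile, for
  within- vs between-network comparisons.
* **Dose–response encoding** — 4PL and bell fits on log concentration,
  EC₂₅/EC₅₀, and a frequency- vs amplitude-encoding verdict from the
  curves' normalized dynamic ranges.
* **Synthetic tissue** — a generator producing Voronoi cell mosaics,
  spatially clustered agonist-sensitive subpopulations with bridge-placed
  multisensitive cells, and neighbor-coupled stochastic Ca²⁺ traces with
  full ground truth, so the whole chain is testable end to end.

The hazard model at the generator's core, for cell *i* at frame *t*:

```
lambda_i(t) = (base_rate + s_i * r(C) * m_i(t)) * (1 + beta * k_i(t))
```

where `s_i` marks sensitivity to the applied agonist, `r(C)` is the
concentration drive (4PL of log C in venous mode, shallow bell in
arterial), `m_i(t)` an optional shared per-community envelope, and `k_i(t)`
counts recently active neighbors. See `docs/methods.md` for every model and
convention.

## Worked example

```python
import numpy as np
from vasonet import SimulationConfig, analyze_dataset, simulate_dataset

config = SimulationConfig(n_cells=150, duration=240.0, concentration=1e-7, rng_seed=3)
ds = simulate_dataset(config, agonists=("ACh",))
bundle = analyze_dataset(ds["traces"]["ACh"], ds["tissue"])

m = bundle["metrics"]
print(f"responders: {len(bundle['responders'].cells)}")
print(f"communities: {m.n_communities}, mean size {m.mean_community_size:.1f}")
pn = bundle["null"]["degree_of_clustering"]
print(f"degree of clustering: {pn.observed:.2f} vs null {pn.null_mean:.2f} "
      f"(percentile {pn.percentile:.0f})")
```

prints (exactly, given the fixed seed):

```
responders: 22
communities: 1, mean size 21.0
degree of clustering: 3.52 vs null 1.53 (percentile 100)
```

22 responders is the top 20% of the 106 interior cells; 21 of them form a
single connected community instead of scattering, and each community
member touches on average 3.52 other active cells — more than any of the
100 random activity placements produced (100th percentile), i.e. the
agonist-sensitive cells are spatially clustered far beyond chance.

The `examples/` directory has one short script per capability (simulation,
detection, communities, centrality bridges, neighbor influence,
cross-correlation, dose–response encoding); each prints the numbers it
computes and says what they mean. A thin CLI mirrors the pipeline for shell
use: `vasonet simulate|detect|graph|communities|centrality|influence|xcorr|dose|all`.

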