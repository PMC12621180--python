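"""Quantify how recent neighbor activity changes a cell's event probability.

Case-control design: positive cases are target events preceded by neighbor
activity within 3x the median FDHM; negative cases are neighbor-activity
windows with a silent target. The temporal permutation null shuffles event
times across cells (counts preserved) to show the coupling is real.
"""

from vasonet import (
    SimulationConfig,
    analyze_dataset,
    build_cases,
    compute_window,
    probability_by_k,
    simulate_dataset,
    temporal_permutation,
)

config = SimulationConfig(
    n_cells=200, coupling_beta=1.0, concentration=1e-7, rng_seed=5
)
ds = simulate_dataset(config, agonists=("ACh",))
bundle = analyze_dataset(ds["traces"]["ACh"], ds["tissue"])
events = bundle["events"]

t_w = compute_window(events)
cases = build_cases(events, ds["tissue"], t_w, bundle["partition"])
curve = probability_by_k(cases, k_values=[1, 2, 3])
null = temporal_permutation(
    events, ds["tissue"], t_w, bundle["partition"], n_perm=100, seed=6,
    k_values=[1, 2, 3],
)

print(f"influence window: {t_w:.1f} s ({len(events)} events)")
print(curve.table)
for k in curve.table.index:
    pn = null[f"p@{k}"]
    print(f"k={k}: observed P={pn.observed:.3f} vs null {pn.null_mean:.3f}")
print(f"slope: {curve.slope:.4f}/neighbor (null {null['slope'].null_mean:.4f})")

# With coupling_beta=1 the observed P(event | k) exceeds the shuffled-time
# null at every neighbor count and rises with k: neighboring activity acts
# as a trigger that raises event likelihood.
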