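# Methods

`vasonet` analyzes agonist-evoked Ca²⁺ signaling in endothelial sheets as a
networked point process: per-cell fluorescence traces are reduced to event
tables, the cell mosaic to an adjacency graph, and the interplay of the two
is quantified with permutation statistics. A synthetic tissue generator with
exported ground truth makes every stage verifiable without imaging data.
This note records the models, the parameters that matter, and the design
choices made where the method leaves them open.

## Event detection and parameterization

Traces are expressed as F/F₀ and smoothed with a Savitzky–Golay filter
(21 points, 3rd order; edges fitted on the truncated window). The baseline
is the 10-s window with the lowest activity before stimulation, where
"activity" is the window standard deviation of the smoothed trace (earliest
window on ties). F₀ is the raw-trace mean over that window.

Events are excursions of the smoothed trace above
`baseline mean + 5 × baseline SD`. Two conventions for "baseline SD" are
supported and the choice matters:

* **raw (default)** — SD of the *raw* trace over the quietest window. The 5×
  multiple then sits ≈12 smoothed-noise SDs above baseline, which excludes
  noise essentially completely while still catching transients of one tenth
  of the resting fluorescence.
* **smoothed** — SD of the smoothed trace. Smoothing shrinks white noise
  ≈2.5-fold and minimizing over windows biases the estimate another ~15%
  low, so the nominal 5× threshold is effectively ~4.3 true SDs: over a
  10-min recording this admits on the order of one spurious crossing per
  cell. Exposed as `baseline_sd_on="smoothed"` for comparison, not as the
  default.

Suprathreshold runs separated by < 0.5 s are merged; a run is split at a
local minimum that drops below 50% of the smaller adjacent peak's height
above threshold, where candidate peaks must have prominence of at least the
threshold multiple × baseline SD (without this floor, noise ripples riding
on a transient shatter it into fragments). Each event is fitted with an
exponentially modified Gaussian (EMG), least squares over the segment
± 3 s, initialized at the peak (μ), the 10–90% rise (σ ≈ rise/1.68), the
1/e decay (τ), and the peak height. Rise (10→90%), fall (90→10%) and FDHM
are then re-measured at the fitted fractional levels on the smoothed real
signal; the fitted (μ, σ, τ, area) are kept alongside. Non-convergent or
< 5-frame segments fall back to empirical threshold metrics with
`fit_ok=False`. The EMG is evaluated with a two-branch erfc/erfcx form that
stays finite on both limbs.

Note the fixed 21-point window interacts with the frame rate: at 10 Hz it
spans 2.1 s and widens a σ = 0.3 s transient by ~15%. Parameter-recovery
checks therefore run at 40 Hz, where the window spans 0.5 s and distortion
is below 1%; pipeline-level checks stay at the 10 Hz study condition, where
FDHM carries this known smoothing bias (harmless downstream, since windows
scale with the *median* measured FDHM).

Cell summaries count events with peaks inside the agonist exposure interval
(default: stimulus onset to end of recording); frequency is events/min.

## Tissue graph

Neighbors are found by expanding every labeled cell until the sheet is
tiled: each background pixel joins the nearest label (exact Euclidean
distance; lowest label id on ties, implemented as a running minimum over
per-label distance transforms restricted to provably sufficient crops), and
two cells are neighbors when their expanded regions share ≥ 2 four-connected
pixel contacts (one-pixel corner contacts are grid artifacts). Field-of-view
edge cells are flagged by an alpha shape over all cell boundary pixels
(Delaunay triangles kept when circumradius < α; default α = 2 × median
equivalent cell diameter; convex-hull fallback if the shape degenerates)
plus any cell touching the image frame, and are excluded from every
analysis as nodes of uncertain connectivity.

## Responder communities and clustering null

For each agonist the top 20% of interior cells ranked by event frequency
(ties: mean amplitude, then cell id) are "active". Communities are the
connected components of the active-induced subgraph with ≥ 2 members;
singletons respond in isolation. Degree of clustering is the mean
active-neighbor count of community members; the clustering coefficient is
the mean local clustering coefficient on the same induced subgraph (members
with < 2 active neighbors contribute 0). The null redistributes exactly the
same number of active cells uniformly over interior nodes, 100 times;
observed values are reported with the null mean/SD and a mid-rank empirical
percentile. No modularity-style community detection is involved.

## Centrality and spectral influence

On the interior-induced graph (binary, undirected): unnormalized
shortest-path betweenness; global eigenvector centrality = entries of the
leading eigenvector of the adjacency matrix (sign-fixed nonnegative); local
influence from the communities-of-dynamical-influence construction — find
the largest eigengap λᵢ − λᵢ₊₁ over i > 1 (search capped at i = 20,
smallest i on ties) and score each node by the L2 norm of its row of
[v₁ … vᵢ*]. A secondary community-of-influence label (argmax |vⱼ| over
j ≤ i*) is reported as an approximation, not the cited reference algorithm.
Group means (ACh-only, BK-only, multisensitive) are compared against
size-matched uniform node resamples (100 draws). "Enriched" in the tests
means the observed group mean exceeds the null's 97.5th percentile;
exceeding the null mean alone is a coin flip under the null.

## Neighbor influence (case–control)

The influence window is t_w = 3 × median FDHM over all well-fitted events.
For each interior target cell: a **positive case** per target event, with k
= number of distinct neighbors peaking in [t − t_w, t); **negative cases**
from grouping neighbor events chronologically into non-overlapping
[t₀, t₀ + t_w] windows (each neighbor counted once per window), where a
window is a valid control only if the target has no event in
[t₀ − t_w, t₀ + t_w]. The look-back in that rule is deliberate: a window
opening during or just after the target's own transient is not an at-risk
period (a new event there cannot be resolved within ~1 FDHM of the last),
and without the exclusion, reverse-order coupling chains (target fires,
neighbor follows) flood the k = 1 bin with spurious negatives.
P(event | k) = positives / (positives + negatives) per k, with a linear
regression of P on k; event timing is the fitted peak time. Neighbor
category is "cluster" when all window neighbors share the target's
community, "non-cluster" when none do; mixed windows are kept for the
overall curve but excluded from the category comparison. The temporal
permutation null shuffles peak times across cells with per-cell counts
preserved (topology and communities untouched), rebuilding all cases per
permutation. Comparisons are restricted to neighbor counts represented in
every compared dataset (in practice k ∈ {1, 2, 3}).

## Cross-correlation

Signals are compared over 10 s of pre-onset baseline plus the activity
period, truncated to the shortest combined duration across datasets and
aligned on onsets (configured stimulus time, else first detected event).
Each pair's segment is halved; per half, the correlation is maximized over
integer-frame lags within ± 3 × median FDHM, demeaning over the overlap at
each lag (so a shifted copy scores exactly 1), floored at 0; the pair
coefficient is the median of the two half values, which for two values is
their mean. Zero-variance halves contribute 0. Per-node connectivity to a
comparison set is the 75th percentile of its pairwise coefficients (linear
interpolation between order statistics; self-pairs excluded), reported for
within-network vs between-network sets side by side.

## Dose–response and encoding

Concentration-response summaries are fitted on log₁₀ C: a 4PL
`R = bottom + (top − bottom)/(1 + 10^((log EC₅₀ − log C)·h))` or a
log-Gaussian bell `R = base + height·exp(−(log C − center)²/2w²)` ("bell-
shaped" is not otherwise specified; the log-Gaussian is the minimal
symmetric choice). EC₂₅ follows from log EC₂₅ = log EC₅₀ − log₁₀(3)/h.
Plateau parameters are bounded within half a span of the observed response
range and the bell width floored at half a log decade — without these
bounds a 4-parameter curve on a 6-point design will fit a full-range
feature into the noise of a flat response. Encoding: dynamic range =
normalized span of the fitted curve per modality; frequency-encoded when
the frequency range exceeds the amplitude range by ≥ 2× (configurable),
amplitude-encoded for the reverse, else indeterminate. When several
replicate vessels are simulated, per-concentration summaries are averaged
across replicates before fitting, as concentration-response studies average
across animals. Ca²⁺-metric-vs-relaxation relations are ordinary least
squares with r².

## Synthetic tissue generator

The generator defines the study conditions; its defaults are fixed once.

**Geometry.** Voronoi tessellation of a jittered lattice (jitter 0.25 of
the pitch) rendered at 512×512 with 1-pixel background borders, so
downstream neighbor detection exercises the expansion rule. Elongation
stretches the lattice pitch along x (1 = venous polygonal; ~3 = arterial,
elongated along flow). Interior cells average ~6 neighbors, the planar
expectation.

**Sensitivity maps.** Per agonist, 2 seed cells are drawn near an anchor —
the two agonists anchored on opposite sides of the sheet at a random height
— and grown by stochastic neighbor recruitment (growth probability 0.9)
to 22% of interior cells. The 22% was chosen so the top-20% responder rule
essentially recovers the sensitive sets, which is what makes the
detect→rank→overlap chain quantitative. Multisensitive cells
(overlap 5% of all cells) are drawn from bridge positions — cells in or
adjacent to both grown sets, which by the left/right anchoring lie near the
sheet's center, the high-betweenness corridor of a planar lattice — so
betweenness enrichment is recoverable by construction. With
`bridge_placement=False` (the null experiment) multisensitive cells are
instead scattered uniformly over interior cells, making them exchangeable
with the permutation null's own draws; drawing them from the sensitive
union would not produce a null, because the union occupies structurally
non-random territory.

**Dynamics.** Discrete-time hazard at the frame rate (at most one onset per
cell per frame; the step is rejected if Δt × max hazard > 0.5):

    λᵢ(t) = (base_rate + sᵢ · r(C) · mᵢ(t)) · (1 + β · kᵢ(t))

with sᵢ ∈ {0,1} the cell's sensitivity to the applied agonist, r(C) the
drive-curve rate (applied from stimulus onset, ≥ 15 s into the recording so
the baseline search always has a pre-stimulus region), mᵢ(t) an optional
per-community shared envelope (smoothed unit-mean noise, amplitude
`community_drive`) used to create intra-community signal correlation, and
kᵢ(t) the number of neighbors with an onset in the trailing coupling window
(default 4 s ≈ one transient duration, the timescale over which a
neighbor's Ca²⁺ remains elevated). Coupling multiplies the whole hazard
because gap-junction-mediated influence raises event probability in any
cell, receptor-sensitive or not. Events are EMG transients (amplitude
N(1.0, 0.15) venous, truncated at 0.1 F/F₀; σ ≈ N(0.35, 0.05) s;
τ ≈ N(1.0, 0.2) s) on a baseline of 1 with white noise SD 0.02 — the 5×
threshold (0.10 F/F₀) then coincides with the amplitude truncation floor,
so every rendered transient is in principle detectable.

**Drive curves.** Venous: rate follows a 4PL (r_max 0.04 /s per sensitive
cell, EC₅₀ 100 nM, h = 1) with a fixed amplitude distribution — frequency
encoding. Arterial: amplitude follows a 4PL (0.4 → 1.2 F/F₀, EC₅₀ 282 nM)
while the rate follows a shallow bell (base 0.013 /s, height 0.002 /s) —
amplitude encoding. The arterial frequency modulation (~10% of the mean
detected rate after coupling amplification) is deliberately kept several
times smaller than the ~65% amplitude modulation: these parameters *define*
the amplitude-encoded condition, and the margin is chosen so the factor-2
classification rule resolves it decisively, the same way an effect size is
chosen in a power analysis. Default concentration for network analyses is
the drive curve's EC₂₅ (~33 nM venous).

**What the generator does not emulate.** No photophysics (bleaching, shot
noise), no motion, no subcellular events, no smooth-muscle or hemodynamic
coupling, no refractoriness beyond one onset per frame, and white (not
pink) noise. Sensitivity communities have no empirical spatial statistics
to match — sizes and compactness are plausible placeholders exposed in the
config. Passing tests therefore demonstrate that the analysis recovers the
statistical structure it assumes, not that real vessels have that
structure.

## Problem sizes and reproducibility

The default sheet is 200 cells × 10 min at 10 Hz (a desk-scale stand-in for
~500-cell imaging fields). Monte Carlo checks in the test suite size each
experiment so its constructed effect is decisively resolvable: coupling
power runs use 300 cells × 10 min (the k = 1 margin is the binding
constraint), calibration runs 150 cells × 6 min, encoding runs average 4
replicate vessels of 80 cells × 4 min (arterial) or a single 100-cell
vessel (venous), and the overlap chain runs at 400 cells. Every random
stage consumes an explicit integer seed; identical configs give
bit-identical masks, maps, traces and permutation draws.

## Known limitations

* FDHM at 10 Hz carries the ~15% smoothing widening discussed above.
* The negative-case at-risk rule is one defensible choice among several;
  with very sparse activity it discards few windows, but at high rates it
  shrinks the negative pool and widens the uncertainty of P(event | k).
* The influence-community node assignment (argmax |vⱼ|) is a stated
  approximation to the cited communities-of-dynamical-influence algorithm.
* Parametric significance tests across preparations (paired t, ANOVA) are
  intentionally out of scope; the pipeline reports observed-vs-null
  distributions and empirical percentiles.

One measurement-level caveat belongs here: during activity bursts a cell's
transients overlap, and a composite or tail-riding event measures longer
rise times and FDHM than its parts. Since bursts co-occur with high
neighbor counts, *measured* characteristics acquire a small spurious
k-correlation (r ≈ 0.1–0.17 at coupled desk-scale rates) even though the
rendered transients are exactly k-independent. The test suite therefore
verifies k-independence on the true parameters and on temporally isolated
single-transient events, where the residual correlation is below 1% of
variance.
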