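"""Synthetic endothelial sheets with ground-truth Ca2+ dynamics.

The generator emulates the statistical structure the analysis pipeline
assumes, with exported ground truth at every stage:

* a Voronoi tessellation of a jittered lattice renders polygonal (venous) or
  elongated (arterial) cells separated by 1-pixel membrane gaps;
* two spatially clustered agonist-sensitive subpopulations are grown from
  seed cells by stochastic neighbor recruitment, with a small multisensitive
  overlap placed preferentially at bridge positions between the two
  communities;
* per-cell Ca2+ event onsets are drawn from a discrete-time hazard that
  rises with agonist drive and with the number of recently active neighbors,
  and each event is rendered as an exponentially modified Gaussian on a
  noisy F/F0 = 1 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .config import AGONISTS, DriveCurve, SimulationConfig
from .events import TraceSet, emg_curve
from .graph import TissueGraph, build_tissue_graph, cell_geometry

__all__ = [
    "GroundTruth",
    "generate_tessellation",
    "assign_sensitivities",
    "drive_rate",
    "drive_amplitude",
    "simulate_traces",
    "simulate_dataset",
]


@dataclass
class GroundTruth:
    """What the generator actually did, for verifying the analysis."""

    sensitivity: dict[int, frozenset[str]]
    communities: dict[str, dict[int, int]]  # agonist -> cell -> community id
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def multisensitive(self) -> set[int]:
        return {c for c, s in self.sensitivity.items() if len(s) == 2}

    def sensitive_to(self, agonist: str) -> set[int]:
        return {c for c, s in self.sensitivity.items() if agonist in s}


def _lattice_seeds(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered lattice seed points (x, y); pitch_x = elongation * pitch_y."""
    h, w = config.render_shape
    n = config.n_cells
    nx_ = max(2, int(round(np.sqrt(n * (w / h) / config.elongation))))
    ny_ = int(np.ceil(n / nx_))
    pitch_x, pitch_y = w / nx_, h / ny_
    jx, jy = config.grid_jitter * pitch_x, config.grid_jitter * pitch_y
    pts = []
    for j in range(ny_):
        for i in range(nx_):
            pts.append(((i + 0.5) * pitch_x, (j + 0.5) * pitch_y))
    pts = np.asarray(pts[:n], dtype=float)
    pts[:, 0] += rng.uniform(-jx, jx, size=n)
    pts[:, 1] += rng.uniform(-jy, jy, size=n)
    return pts


def generate_tessellation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the label mask (1-px background borders) and per-cell geometry.

    Cells are the Voronoi regions of the jittered lattice; elongation > 1
    stretches the lattice pitch along x so regions are elongated along the
    flow axis. Labels are 1..n_cells in lattice order.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    h, w = config.render_shape
    seeds = None
    for _ in range(5):
        cand = _lattice_seeds(config, rng)
        d, _idx = cKDTree(cand).query(cand, k=2)
        if d[:, 1].min() > 1e-9:
            seeds = cand
            break
    if seeds is None:
        raise RuntimeError("could not draw non-coincident tessellation seeds")

    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.stack([xx.ravel() + 0.5, yy.ravel() + 0.5], axis=1)
    _, owner = cKDTree(seeds).query(pix)
    lab = (owner + 1).astype(np.int32).reshape(h, w)

    border = np.zeros((h, w), dtype=bool)
    border[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    border[:-1, :] |= lab[:-1, :] != lab[1:, :]
    mask = np.where(border, 0, lab).astype(np.int32)
    return mask, cell_geometry(mask)


def _grow_community(
    graph, interior: set[int], seeds: list[int], target: int, growth_prob: float,
    anchor_order: list[int], rng: np.random.Generator,
) -> set[int]:
    """Grow a connected set from seeds by stochastic neighbor recruitment."""
    grown = set(seeds)
    while len(grown) < target:
        frontier = sorted(
            {nb for c in grown for nb in graph.neighbors(c)} & interior - grown
        )
        if not frontier:
            # grown set exhausted its component; jump to the nearest unused cell
            rest = [c for c in anchor_order if c not in grown]
            if not rest:
                break
            grown.add(rest[0])
            continue
        added = 0
        for f in rng.permutation(frontier):
            if len(grown) >= target:
                break
            if rng.random() < growth_prob:
                grown.add(int(f))
                added += 1
        if added == 0 and len(grown) < target:
            grown.add(int(rng.choice(frontier)))  # guarantee progress
    return grown


def assign_sensitivities(
    tg: TissueGraph,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Grow clustered sensitive subpopulations and place the multisensitive overlap.

    Seeds for the two agonists are anchored on opposite sides of the sheet so
    that, with ``bridge_placement``, multisensitive cells end up near the
    center of the sheet where the two communities meet.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    interior = set(tg.interior)
    if not interior:
        raise ValueError("no interior cells to assign sensitivities to")
    geom = tg.geometry
    n_interior = len(interior)
    target = max(config.community_seeds, int(round(config.sensitive_frac * n_interior)))

    cols = geom.loc[sorted(interior), "col"]
    rows = geom.loc[sorted(interior), "row"]
    # one community per side of the sheet; the anchor row is randomized so the
    # sensitive populations themselves are not systematically central
    anchors = {
        AGONISTS[0]: (float(cols.quantile(0.25)), float(rows.quantile(rng.uniform(0.2, 0.8)))),
        AGONISTS[1]: (float(cols.quantile(0.75)), float(rows.quantile(rng.uniform(0.2, 0.8)))),
    }

    grown: dict[str, set[int]] = {}
    for agonist in AGONISTS:
        ax, ay = anchors[agonist]
        order = sorted(
            interior,
            key=lambda c: (geom.at[c, "col"] - ax) ** 2 + (geom.at[c, "row"] - ay) ** 2,
        )
        pool = order[: max(3 * config.community_seeds, config.community_seeds)]
        seeds = [int(c) for c in rng.choice(pool, size=config.community_seeds, replace=False)]
        grown[agonist] = _grow_community(
            tg.graph, interior, seeds, target, config.growth_prob, order, rng
        )

    a_set, b_set = grown[AGONISTS[0]], grown[AGONISTS[1]]
    n_multi = int(round(config.overlap_frac * config.n_cells))
    multi: set[int] = set()
    if n_multi > 0:
        union = a_set | b_set
        if n_multi > len(union):
            raise ValueError(
                f"overlap_frac {config.overlap_frac} requires {n_multi} multisensitive "
                f"cells but only {len(union)} cells are sensitive"
            )
        if config.bridge_placement:
            def touches(c: int, other: set[int]) -> bool:
                return any(nb in other for nb in tg.graph.neighbors(c))

            candidates = sorted(
                c for c in interior
                if (c in a_set and touches(c, b_set))
                or (c in b_set and touches(c, a_set))
                or (c not in union and touches(c, a_set) and touches(c, b_set))
            )
        else:
            # null experiment: multisensitive cells scattered uniformly over the
            # interior, exchangeable with random-position permutation draws
            candidates = sorted(interior)
        take = min(n_multi, len(candidates))
        multi = {int(c) for c in rng.choice(candidates, size=take, replace=False)}
        if len(multi) < n_multi:  # bridge pool exhausted; fall back to members
            rest = sorted(union - multi)
            extra = rng.choice(rest, size=n_multi - len(multi), replace=False)
            multi |= {int(c) for c in extra}
        a_set |= multi
        b_set |= multi

    sensitivity: dict[int, frozenset[str]] = {}
    for c in sorted(tg.graph.nodes):
        s = set()
        if c in a_set:
            s.add(AGONISTS[0])
        if c in b_set:
            s.add(AGONISTS[1])
        sensitivity[int(c)] = frozenset(s)

    import networkx as nx

    communities: dict[str, dict[int, int]] = {}
    for agonist, cells in ((AGONISTS[0], a_set), (AGONISTS[1], b_set)):
        comp_map: dict[int, int] = {}
        sub = tg.graph.subgraph(cells)
        for i, comp in enumerate(sorted(nx.connected_components(sub), key=min)):
            for c in comp:
                comp_map[int(c)] = i
        communities[agonist] = comp_map
    return GroundTruth(sensitivity=sensitivity, communities=communities)


def drive_rate(curve: DriveCurve, concentration: float) -> float:
    """Agonist-driven event rate (events/s) for a sensitive cell."""
    logc = np.log10(concentration)
    if curve.mode == "venous":
        return curve.rate_max / (
            1.0 + 10.0 ** ((curve.rate_log10_ec50 - logc) * curve.rate_hill)
        )
    return curve.bell_rate_base + curve.bell_rate_height * np.exp(
        -((logc - curve.bell_center) ** 2) / (2.0 * curve.bell_width**2)
    )


def drive_amplitude(curve: DriveCurve, concentration: float) -> float | None:
    """Mean event amplitude; None in venous mode (fixed distribution)."""
    if curve.mode == "venous":
        return None
    logc = np.log10(concentration)
    return curve.amp_bottom + (curve.amp_top - curve.amp_bottom) / (
        1.0 + 10.0 ** ((curve.amp_log10_ec50 - logc) * curve.amp_hill)
    )


TRUE_EVENT_COLUMNS = ["cell_id", "onset", "peak_time", "amplitude", "sigma", "tau"]


def simulate_traces(
    truth: GroundTruth,
    tg: TissueGraph,
    config: SimulationConfig,
    agonist: str = "ACh",
    concentration: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TraceSet, pd.DataFrame]:
    """Draw event onsets from the neighbor-coupled hazard and render traces.

    The per-cell hazard at frame t is::

        lambda_i(t) = (base_rate + s_i * r(C) * m_i(t)) * (1 + beta * k_i(t))

    with ``s_i`` the cell's sensitivity to the applied agonist, ``r(C)`` the
    drive-curve rate at concentration C (applied from the stimulus onset),
    ``m_i(t)`` an optional shared per-community envelope, and ``k_i(t)`` the
    number of neighbors with an onset within the coupling window. Neighbor
    coupling multiplies the whole hazard: gap-junction-mediated influence
    raises event probability in any cell, sensitive or not. At most one
    onset per cell per frame; events are EMG transients added to a baseline
    of 1 plus white Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    conc = concentration if concentration is not None else config.concentration_or_ec25
    dt = 1.0 / config.frame_rate
    n_frames = int(round(config.duration * config.frame_rate))
    cell_ids = sorted(int(c) for c in tg.graph.nodes)
    n = len(cell_ids)
    index = {c: i for i, c in enumerate(cell_ids)}

    s = np.array([1.0 if agonist in truth.sensitivity.get(c, frozenset()) else 0.0
                  for c in cell_ids])
    r_c = drive_rate(config.drive_curve, conc)
    amp_mean = drive_amplitude(config.drive_curve, conc)
    if amp_mean is None:
        amp_mean = config.amp_mean

    # shared per-community rate envelope (unit mean), for correlated drive
    comm = truth.communities.get(agonist, {})
    comm_ids = sorted(set(comm.values()))
    envelopes: dict[int, np.ndarray] = {}
    if config.community_drive > 0:
        for cid in comm_ids:
            white = rng.standard_normal(n_frames)
            env = gaussian_filter1d(white, sigma=2.0 * config.frame_rate)
            sd = env.std()
            if sd > 0:
                env = env / sd
            envelopes[cid] = np.maximum(0.0, 1.0 + config.community_drive * env)
    env_matrix = None
    if envelopes:
        env_matrix = np.ones((n_frames, n), dtype=float)
        for i, c in enumerate(cell_ids):
            cid = comm.get(c)
            if cid is not None:
                env_matrix[:, i] = envelopes[cid]

    neighbor_lists = [np.array([index[nb] for nb in tg.graph.neighbors(c)], dtype=int)
                      for c in cell_ids]
    win_frames = max(1, int(round(config.coupling_window * config.frame_rate)))
    onset_frame = int(round(config.stimulus_onset * config.frame_rate))

    max_rate = config.base_rate + s.max(initial=0.0) * r_c * (
        1.0 + config.coupling_beta * max((len(nl) for nl in neighbor_lists), default=0)
    ) * (1.0 + 2.0 * config.community_drive)
    if max_rate * dt > 0.5:
        raise ValueError(
            f"frame step too coarse: max hazard x dt = {max_rate * dt:.3f} > 0.5"
        )

    k = np.zeros(n, dtype=float)
    expiry: list[list[int]] = [[] for _ in range(n_frames + win_frames + 1)]
    onsets: list[tuple[int, int]] = []  # (frame, cell index)
    for f in range(n_frames):
        for i in expiry[f]:
            k[i] -= 1.0
        if f >= onset_frame:
            drive = s * r_c * (env_matrix[f] if env_matrix is not None else 1.0)
        else:
            drive = 0.0
        lam = (config.base_rate + drive) * (1.0 + config.coupling_beta * k)
        fired = np.flatnonzero(rng.random(n) < lam * dt)
        for i in fired:
            onsets.append((f, int(i)))
            for nb in neighbor_lists[i]:
                k[nb] += 1.0
                expiry[f + win_frames].append(int(nb))

    # render transients
    time = np.arange(n_frames) * dt
    values = np.ones((n_frames, n), dtype=float)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=(n_frames, n))
    rows = []
    for f, i in onsets:
        amp = max(config.amp_min, rng.normal(amp_mean, config.amp_sd))
        sigma = max(0.05, rng.normal(config.sigma_mean, config.sigma_sd))
        tau = max(0.05, rng.normal(config.tau_mean, config.tau_sd))
        t0 = f * dt
        mu = t0 + 2.5 * sigma  # transient starts (~mu - 2.5 sigma) at the onset frame
        span = mu + 6.0 * tau + 4.0 * sigma - t0
        hi = min(n_frames, f + int(np.ceil(span * config.frame_rate)) + 1)
        tt = time[f:hi]
        fine = np.arange(t0, t0 + span, dt / 5.0)
        kernel_fine = emg_curve(fine, mu, sigma, tau, 1.0)
        peak_val = kernel_fine.max()
        peak_time = float(fine[int(np.argmax(kernel_fine))])
        if peak_val <= 0:
            continue
        values[f:hi, i] += amp * emg_curve(tt, mu, sigma, tau, 1.0) / peak_val
        rows.append((cell_ids[i], t0, peak_time, amp, sigma, tau))

    events = pd.DataFrame(rows, columns=TRUE_EVENT_COLUMNS)
    traces = TraceSet(
        time=time,
        values=values,
        frame_rate=config.frame_rate,
        cell_ids=cell_ids,
        stimulus_onset=config.stimulus_onset,
    )
    return traces, events


def simulate_dataset(
    config: SimulationConfig,
    agonists: tuple[str, ...] = AGONISTS,
    concentration: float | None = None,
    seed: int | None = None,
) -> dict:
    """Tessellation + sensitivity map + one trace set per agonist.

    Returns a dict with ``mask``, ``tissue`` (TissueGraph), ``truth``
    (GroundTruth with per-agonist events) and ``traces``/``events`` keyed by
    agonist. Fully deterministic given the config seed.
    """
    root = np.random.default_rng(config.rng_seed if seed is None else seed)
    streams = root.spawn(2 + len(agonists))
    mask, _geom = generate_tessellation(config, streams[0])
    tg = build_tissue_graph(mask)
    truth = assign_sensitivities(tg, config, streams[1])
    out = {"mask": mask, "tissue": tg, "truth": truth, "traces": {}, "events": {}}
    all_events = []
    for i, agonist in enumerate(agonists):
        traces, events = simulate_traces(
            truth, tg, config, agonist=agonist, concentration=concentration,
            rng=streams[2 + i],
        )
        out["traces"][agonist] = traces
        out["events"][agonist] = events
        ev = events.copy()
        ev["agonist"] = agonist
        all_events.append(ev)
    truth.events = pd.concat(all_events, ignore_index=True) if all_events else pd.DataFrame()
    return out
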