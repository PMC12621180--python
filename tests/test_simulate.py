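"""Synthetic tissue generator: tessellation, sensitivity maps, hazard model."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vasonet.config import SimulationConfig
from vasonet.graph import TissueGraph, build_tissue_graph
from vasonet.simulate import (
    assign_sensitivities,
    generate_tessellation,
    simulate_dataset,
    simulate_traces,
)


def path_tissue(n):
    g = nx.path_graph(n)
    geom = pd.DataFrame(
        {"cell_id": range(n), "row": 0.0, "col": np.arange(n, dtype=float)}
    ).set_index("cell_id", drop=False)
    return TissueGraph(graph=g, boundary=set(), geometry=geom)


class TestTessellation:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_cells=60, render_shape=(160, 160), rng_seed=5)
        m1, _ = generate_tessellation(cfg)
        m2, _ = generate_tessellation(cfg)
        assert np.array_equal(m1, m2)

    def test_square_lattice_no_jitter_near_square_cells(self):
        cfg = SimulationConfig(n_cells=25, render_shape=(200, 200), grid_jitter=0.0, rng_seed=0)
        _, geom = generate_tessellation(cfg)
        inner = geom.iloc[6:19]  # skip frame-clipped cells
        assert inner["ratio"].mean() < 1.1

    def test_elongation_increases_aspect_ratio(self):
        base = SimulationConfig(n_cells=60, render_shape=(200, 200), rng_seed=1)
        elong = SimulationConfig(
            n_cells=60, render_shape=(200, 200), rng_seed=1, elongation=3.0
        )
        _, g1 = generate_tessellation(base)
        _, g3 = generate_tessellation(elong)
        assert g3["ratio"].mean() > g1["ratio"].mean()

    def test_region_count_and_connectivity(self):
        cfg = SimulationConfig(n_cells=40, render_shape=(160, 160), rng_seed=2)
        mask, _ = generate_tessellation(cfg)
        labels = np.unique(mask)
        assert labels.max() == 40 and (labels[1:] == np.arange(1, 41)).all()

    def test_mean_neighbor_count_matches_planar_expectation(self):
        # interior Voronoi cells average ~6 neighbors on a jittered lattice
        cfg = SimulationConfig(n_cells=220, rng_seed=11)
        mask, _ = generate_tessellation(cfg)
        tg = build_tissue_graph(mask)
        deg = np.mean([tg.graph.degree(c) for c in tg.interior])
        assert 5.5 <= deg <= 6.5


class TestSensitivities:
    def test_full_growth_on_path_is_contiguous(self):
        tg = path_tissue(12)
        cfg = SimulationConfig(
            n_cells=12, growth_prob=1.0, community_seeds=1, overlap_frac=0.0,
            sensitive_frac=0.25, rng_seed=0,
        )
        truth = assign_sensitivities(tg, cfg)
        for agonist in ("ACh", "BK"):
            cells = sorted(truth.sensitive_to(agonist))
            assert cells == list(range(cells[0], cells[-1] + 1))

    def test_zero_overlap_gives_disjoint_sets(self, tissue):
        cfg = SimulationConfig(n_cells=80, overlap_frac=0.0, rng_seed=3)
        truth = assign_sensitivities(tissue, cfg)
        assert truth.sensitive_to("ACh") & truth.sensitive_to("BK") == set()

    def test_overlap_count_matches_fraction(self, tissue):
        cfg = SimulationConfig(n_cells=80, overlap_frac=0.05, rng_seed=3)
        truth = assign_sensitivities(tissue, cfg)
        assert len(truth.multisensitive()) == 4  # round(0.05 * 80)

    def test_unachievable_overlap_rejected(self):
        tg = path_tissue(10)
        cfg = SimulationConfig(
            n_cells=10, overlap_frac=0.9, sensitive_frac=0.2, community_seeds=1, rng_seed=0
        )
        with pytest.raises(ValueError):
            assign_sensitivities(tg, cfg)


class TestTraces:
    def test_insensitive_cell_flat_without_noise(self):
        cfg = SimulationConfig(
            n_cells=9, render_shape=(64, 64), duration=60.0, noise_sd=0.0,
            base_rate=0.0, overlap_frac=0.0, sensitive_frac=0.12,
            community_seeds=1, rng_seed=4,
        )
        ds = simulate_dataset(cfg, agonists=("ACh",))
        truth, traces = ds["truth"], ds["traces"]["ACh"]
        insensitive = [
            c for c in traces.cell_ids if "ACh" not in truth.sensitivity[c]
        ]
        assert insensitive
        for c in insensitive[:3]:
            assert np.allclose(traces.column(c), 1.0)

    def test_event_count_matches_rendered_transients(self):
        cfg = SimulationConfig(n_cells=16, render_shape=(96, 96), duration=80.0, rng_seed=5)
        ds = simulate_dataset(cfg, agonists=("ACh",))
        ev = ds["events"]["ACh"]
        assert (ev.onset >= 0).all() and (ev.onset <= cfg.duration).all()

    def test_deterministic_traces(self):
        cfg = SimulationConfig(n_cells=12, render_shape=(96, 96), duration=60.0, rng_seed=6)
        d1 = simulate_dataset(cfg, agonists=("ACh",))
        d2 = simulate_dataset(cfg, agonists=("ACh",))
        assert np.array_equal(d1["traces"]["ACh"].values, d2["traces"]["ACh"].values)
        pd.testing.assert_frame_equal(d1["events"]["ACh"], d2["events"]["ACh"])

    def test_uncoupled_event_rate_matches_poisson_mean(self):
        # closed-form oracle: with beta=0 the per-cell count is Poisson with
        # mean base*T + s*r(C)*(T - onset)
        cfg = SimulationConfig(
            n_cells=16, render_shape=(96, 96), duration=120.0, coupling_beta=0.0,
            base_rate=0.01, noise_sd=0.0, concentration=1e-5, rng_seed=0,
        )
        from vasonet.simulate import drive_rate

        r = drive_rate(cfg.drive_curve, 1e-5)
        root = np.random.default_rng(123)
        mask, _ = generate_tessellation(cfg, root.spawn(1)[0])
        tg = build_tissue_graph(mask)
        truth = assign_sensitivities(tg, cfg, np.random.default_rng(1))
        total = 0.0
        expected = 0.0
        reps = 25
        for i in range(reps):
            _, ev = simulate_traces(
                truth, tg, cfg, agonist="ACh", rng=np.random.default_rng(1000 + i)
            )
            total += len(ev)
        for c in sorted(tg.graph.nodes):
            s = 1.0 if "ACh" in truth.sensitivity[c] else 0.0
            expected += cfg.base_rate * cfg.duration + s * r * (
                cfg.duration - cfg.stimulus_onset
            )
        se = np.sqrt(expected * reps)  # Poisson SE of the summed count
        assert abs(total - expected * reps) <= 3 * se

    def test_too_coarse_hazard_rejected(self, tissue):
        cfg = SimulationConfig(n_cells=80, base_rate=8.0, rng_seed=0)
        truth = assign_sensitivities(tissue, cfg)
        with pytest.raises(ValueError):
            simulate_traces(truth, tissue, cfg)

    def test_coupled_event_probability_nondecreasing_in_k(self, small_dataset):
        # beta > 0: empirical next-frame onset probability rises with the
        # number of recently active neighbors (checked on generator output)
        cfg = SimulationConfig(n_cells=80, duration=180.0, render_shape=(288, 288),
                               rng_seed=7, concentration=1e-7)
        tg = small_dataset["tissue"]
        ev = small_dataset["events"]["ACh"]
        win = cfg.coupling_window
        onsets = {c: g.onset.to_numpy() for c, g in ev.groupby("cell_id")}
        dt = 1.0 / cfg.frame_rate
        frames = np.arange(cfg.stimulus_onset, cfg.duration - dt, dt)
        probs = {}
        rng = np.random.default_rng(0)
        sample = rng.choice(frames, size=4000)
        for c in tg.interior:
            nbr = tg.neighbors(c)
            own = onsets.get(c, np.empty(0))
            for t in sample[:1000]:
                k = sum(
                    1 for nb in nbr
                    if nb in onsets and np.any((onsets[nb] > t - win) & (onsets[nb] <= t))
                )
                fired = np.any((own > t) & (own <= t + dt))
                hit, n = probs.get(k, (0, 0))
                probs[k] = (hit + fired, n + 1)
        ks = sorted(k for k, (h, n) in probs.items() if n >= 200)[:3]
        rates = [probs[k][0] / probs[k][1] for k in ks]
        assert all(b >= a * 0.8 for a, b in zip(rates, rates[1:]))
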