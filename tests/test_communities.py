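"""Responder selection, community partitioning and permutation nulls."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vasonet.communities import (
    ResponderSet,
    community_metrics,
    find_communities,
    permutation_null,
    select_top_responders,
)

from conftest import toy_graph


def summaries_frame(freqs, amps=None):
    n = len(freqs)
    amps = amps if amps is not None else [1.0] * n
    df = pd.DataFrame(
        {
            "cell_id": range(n),
            "event_count": [int(f) for f in freqs],
            "frequency": freqs,
            "mean_amplitude": amps,
            "median_fdhm": [1.5] * n,
        }
    ).set_index("cell_id", drop=False)
    return df


def oracle_metrics(graph, responders):
    """Brute-force recomputation with explicit loops."""
    active = set(responders)
    comps = []
    seen = set()
    for c in active:
        if c in seen:
            continue
        comp = {c}
        frontier = [c]
        while frontier:
            x = frontier.pop()
            for nb in graph.neighbors(x):
                if nb in active and nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        comps.append(comp)
    communities = [c for c in comps if len(c) >= 2]
    isolated = [c for c in comps if len(c) == 1]
    members = set().union(*communities) if communities else set()
    degs, ccs = [], []
    for m in members:
        nbrs = [nb for nb in graph.neighbors(m) if nb in active]
        degs.append(len(nbrs))
        if len(nbrs) < 2:
            ccs.append(0.0)
        else:
            links = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if graph.has_edge(a, b)
            )
            ccs.append(2 * links / (len(nbrs) * (len(nbrs) - 1)))
    return {
        "n_communities": len(communities),
        "mean_size": np.mean([len(c) for c in communities]) if communities else 0.0,
        "n_isolated": len(isolated),
        "degree": np.mean(degs) if degs else 0.0,
        "cc": np.mean(ccs) if ccs else 0.0,
    }


class TestSelection:
    def test_top_fraction_by_frequency(self):
        tg = toy_graph([(i, i + 1) for i in range(9)])
        s = summaries_frame([0, 5, 1, 9, 2, 3, 8, 4, 6, 7])
        top = select_top_responders(s, tg, 0.2)
        assert set(top.cells) == {3, 6}

    def test_tie_break_by_amplitude_then_id(self):
        tg = toy_graph([(i, i + 1) for i in range(4)])
        s = summaries_frame([1.0, 1.0, 1.0, 1.0, 1.0], amps=[0.1, 0.9, 0.5, 0.9, 0.2])
        top = select_top_responders(s, tg, 0.4)
        assert top.cells == [1, 3]  # equal frequency: amplitude desc, id asc

    def test_fraction_one_selects_everyone(self):
        tg = toy_graph([(i, i + 1) for i in range(5)])
        s = summaries_frame([1, 2, 3, 4, 5, 6])
        top = select_top_responders(s, tg, 1.0)
        assert set(top.cells) == set(tg.interior)


class TestPartition:
    def test_adjacent_pair_forms_community(self):
        tg = toy_graph([(0, 1), (1, 2), (2, 3)])
        part = find_communities(tg, ResponderSet("ACh", [0, 1]))
        assert part.communities == [{0, 1}]
        assert part.isolated == set()

    def test_scattered_actives_are_isolated(self):
        tg = toy_graph([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        part = find_communities(tg, ResponderSet("ACh", [0, 2, 4]))
        assert part.communities == []
        assert part.isolated == {0, 2, 4}

    def test_active_path_single_community(self):
        tg = toy_graph([(0, 1), (1, 2), (2, 3)])
        part = find_communities(tg, ResponderSet("ACh", [0, 1, 2]))
        assert part.communities == [{0, 1, 2}]

    def test_order_invariance(self):
        tg = toy_graph([(0, 1), (1, 2), (3, 4), (4, 5), (2, 3)])
        cells = [5, 1, 3, 0]
        p1 = find_communities(tg, ResponderSet("ACh", cells))
        p2 = find_communities(tg, ResponderSet("ACh", cells[::-1]))
        assert p1.communities == p2.communities and p1.isolated == p2.isolated

    def test_non_interior_responder_rejected(self):
        tg = toy_graph([(0, 1), (1, 2)], boundary={2})
        with pytest.raises(ValueError):
            find_communities(tg, ResponderSet("ACh", [1, 2]))


class TestMetrics:
    def test_triangle(self):
        tg = toy_graph([(0, 1), (1, 2), (0, 2), (2, 3)])
        part = find_communities(tg, ResponderSet("ACh", [0, 1, 2]))
        m = community_metrics(tg, part)
        assert m.degree_of_clustering == pytest.approx(2.0)
        assert m.clustering_coefficient == pytest.approx(1.0)

    def test_path_of_three(self):
        tg = toy_graph([(0, 1), (1, 2), (2, 3)])
        part = find_communities(tg, ResponderSet("ACh", [0, 1, 2]))
        m = community_metrics(tg, part)
        assert m.degree_of_clustering == pytest.approx(4.0 / 3.0)
        assert m.clustering_coefficient == pytest.approx(0.0)

    def test_empty_partition_flagged(self):
        tg = toy_graph([(0, 1), (1, 2)])
        part = find_communities(tg, ResponderSet("ACh", [0]))
        m = community_metrics(tg, part)
        assert m.empty and m.degree_of_clustering == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(10, 0.35, seed=seed)
        tg = toy_graph(g.edges())
        tg.graph.add_nodes_from(g.nodes())
        active = [int(c) for c in rng.choice(10, size=5, replace=False)]
        part = find_communities(tg, ResponderSet("x", active))
        m = community_metrics(tg, part)
        o = oracle_metrics(g, active)
        assert m.n_communities == o["n_communities"]
        assert m.n_isolated == o["n_isolated"]
        assert m.mean_community_size == pytest.approx(o["mean_size"])
        assert m.degree_of_clustering == pytest.approx(o["degree"])
        assert m.clustering_coefficient == pytest.approx(o["cc"])

    def test_partition_accounting_identity(self):
        # mean_size * n_communities + n_isolated = |responders|
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.3, seed=4)
        tg = toy_graph(g.edges())
        tg.graph.add_nodes_from(g.nodes())
        for _ in range(10):
            active = [int(c) for c in rng.choice(12, size=6, replace=False)]
            part = find_communities(tg, ResponderSet("x", active))
            m = community_metrics(tg, part)
            total = m.mean_community_size * m.n_communities + m.n_isolated
            assert total == pytest.approx(len(active))


class TestPermutationNull:
    def test_null_mean_matches_exhaustive_enumeration(self):
        # tiny graph: compare the sampled null against all C(6,3) active sets
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (1, 4)])
        tg = toy_graph(g.edges())
        exact = []
        for combo in itertools.combinations(range(6), 3):
            part = find_communities(tg, ResponderSet("x", list(combo)))
            exact.append(community_metrics(tg, part).degree_of_clustering)
        exact_mean = np.mean(exact)
        null = permutation_null(tg, 3, n_perm=3000, seed=0)
        sampled = null["degree_of_clustering"]
        se = np.std(exact) / np.sqrt(3000)
        assert abs(sampled.null_mean - exact_mean) < 4 * se + 1e-12

    def test_single_permutation_reproducible(self):
        g = nx.path_graph(8)
        tg = toy_graph(g.edges())
        n1 = permutation_null(tg, 3, n_perm=1, seed=42)
        n2 = permutation_null(tg, 3, n_perm=1, seed=42)
        assert n1["degree_of_clustering"].values == n2["degree_of_clustering"].values

    def test_percentile_midrank(self):
        from vasonet.communities import PermutationNull

        pn = PermutationNull("m", observed=2.0, values=np.array([1.0, 2.0, 3.0, 2.0]))
        # one below, two equal -> (1 + 1) / 4 = 50%
        assert pn.percentile == pytest.approx(50.0)
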