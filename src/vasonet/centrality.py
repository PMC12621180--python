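"""Betweenness, eigenvector centrality, eigengap and local influence.

Centralities are computed on the interior-node induced graph with binary
edges. Betweenness is the unnormalized shortest-path form. The global
eigenvector centrality is the leading eigenvector of the adjacency matrix;
local influence uses the eigenvectors up to the largest eigengap (the
communities-of-dynamical-influence construction): each node's score is the
L2 norm of its row of [v1 ... v_i*]. Group enrichment (ACh-only, BK-only,
multisensitive) is assessed against uniform node-resampling nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .communities import PermutationNull
from .graph import TissueGraph

__all__ = [
    "SpectralSummary",
    "betweenness",
    "spectral_summary",
    "local_influence",
    "centrality_table",
    "group_centrality",
    "centrality_permutation",
]

CENTRALITY_COLUMNS = ("betweenness", "global_eigen", "local_influence")


@dataclass
class SpectralSummary:
    """Eigendecomposition of the (symmetric) interior adjacency matrix.

    Eigenvalues are sorted descending; eigenvectors are unit-norm columns of
    ``vectors`` with the leading one sign-fixed nonnegative. ``eigengap_index``
    is the i > 1 maximizing lambda_i - lambda_(i+1) (1-based, smallest i on
    ties, search bounded at 20 for stability).
    """

    nodes: list[int]
    eigenvalues: np.ndarray
    vectors: np.ndarray
    eigengaps: np.ndarray
    eigengap_index: int
    connected: bool = True


def betweenness(tg: TissueGraph) -> pd.Series:
    """Unnormalized shortest-path betweenness of interior nodes."""
    g = tg.interior_graph()
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="betweenness").sort_index()


def spectral_summary(tg: TissueGraph, max_gap_index: int = 20) -> SpectralSummary:
    nodes = tg.interior
    if len(nodes) < 2:
        raise ValueError("need >= 2 interior nodes for a spectral summary")
    g = tg.interior_graph()
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    vals, vecs = np.linalg.eigh(a)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # Perron vector of a connected graph has one sign; fix it nonnegative
    lead = vecs[:, 0]
    if lead[np.argmax(np.abs(lead))] < 0:
        vecs[:, 0] = -lead
    vecs[:, 0] = np.abs(vecs[:, 0]) if np.all(vecs[:, 0] >= -1e-12) else vecs[:, 0]
    gaps = vals[:-1] - vals[1:]  # gaps[i-1] = lambda_i - lambda_(i+1), 1-based i
    hi = min(len(gaps), max_gap_index)
    if hi >= 2:
        i_star = int(np.argmax(gaps[1:hi])) + 2  # i > 1, smallest index on ties
    else:
        i_star = 1
    return SpectralSummary(
        nodes=nodes,
        eigenvalues=vals,
        vectors=vecs,
        eigengaps=gaps,
        eigengap_index=i_star,
        connected=nx.is_connected(g) if len(nodes) else True,
    )


def local_influence(spectral: SpectralSummary) -> pd.DataFrame:
    """Per-node L2 norm over the leading eigenvectors v1..v_i*.

    Also reports a secondary community-of-influence assignment: the index
    j <= i* whose eigenvector carries the node's largest |component|.
    """
    k = spectral.eigengap_index
    block = spectral.vectors[:, :k]
    score = np.linalg.norm(block, axis=1)
    assign = np.argmax(np.abs(block), axis=1) + 1
    return pd.DataFrame(
        {"local_influence": score, "influence_community": assign},
        index=pd.Index(spectral.nodes, name="cell_id"),
    )


def centrality_table(tg: TissueGraph) -> pd.DataFrame:
    """Betweenness, global eigenvector centrality and local influence per interior node."""
    spec = spectral_summary(tg)
    bc = betweenness(tg)
    li = local_influence(spec)
    out = pd.DataFrame(
        {
            "betweenness": bc,
            "global_eigen": pd.Series(np.abs(spec.vectors[:, 0]), index=spec.nodes),
            "local_influence": li["local_influence"],
            "influence_community": li["influence_community"],
        }
    )
    out.index.name = "cell_id"
    return out


def group_centrality(
    table: pd.DataFrame,
    responders_a: set[int],
    responders_b: set[int],
    labels: tuple[str, str] = ("ACh", "BK"),
) -> pd.DataFrame:
    """Mean centralities of agonist-exclusive and multisensitive groups."""
    groups = {
        f"{labels[0]}-only": set(responders_a) - set(responders_b),
        f"{labels[1]}-only": set(responders_b) - set(responders_a),
        "multisensitive": set(responders_a) & set(responders_b),
    }
    rows = []
    for name, cells in groups.items():
        cells = cells & set(table.index)
        if not cells:
            rows.append({"group": name, "n": 0, **{c: np.nan for c in CENTRALITY_COLUMNS}})
            continue
        sub = table.loc[sorted(cells)]
        rows.append(
            {"group": name, "n": len(cells), **{c: float(sub[c].mean()) for c in CENTRALITY_COLUMNS}}
        )
    return pd.DataFrame(rows).set_index("group")


def centrality_permutation(
    tg: TissueGraph,
    group_sizes: dict[str, int],
    n_perm: int = 100,
    seed: int = 0,
    table: pd.DataFrame | None = None,
    observed: pd.DataFrame | None = None,
) -> dict[tuple[str, str], PermutationNull]:
    """Uniform node-resampling null for group-mean centralities.

    For each group, ``n_perm`` random interior-node sets of the matched size
    are drawn and the group means recomputed; returns one null per
    (group, centrality) pair.
    """
    if table is None:
        table = centrality_table(tg)
    interior = np.array(tg.interior)
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], PermutationNull] = {}
    for group, size in group_sizes.items():
        if size > interior.size:
            raise ValueError(f"group {group!r} larger than the interior set")
        if size == 0:
            continue
        draws = {c: np.empty(n_perm) for c in CENTRALITY_COLUMNS}
        for p in range(n_perm):
            cells = rng.choice(interior, size=size, replace=False)
            sub = table.loc[cells]
            for c in CENTRALITY_COLUMNS:
                draws[c][p] = float(sub[c].mean())
        for c in CENTRALITY_COLUMNS:
            obs = np.nan
            if observed is not None and group in observed.index:
                obs = float(observed.at[group, c])
            out[(group, c)] = PermutationNull(
                metric=f"{group}:{c}", observed=obs, values=draws[c], seed=seed
            )
    return out
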