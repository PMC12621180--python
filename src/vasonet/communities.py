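"""Top-responder selection, spatial communities and permutation nulls.

The most agonist-sensitive cells (top 20% of interior cells ranked by event
frequency) are mapped onto the tissue graph; connected groups of active
cells form communities, active cells with no active neighbor respond in
isolation. Clustering metrics are compared against a null built by randomly
reassigning activity across interior cells (same number of active cells,
100 permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import TissueGraph

__all__ = [
    "ResponderSet",
    "CommunityPartition",
    "CommunityMetrics",
    "PermutationNull",
    "select_top_responders",
    "find_communities",
    "community_metrics",
    "permutation_null",
]


@dataclass
class ResponderSet:
    agonist: str
    cells: list[int]

    def __contains__(self, cell: int) -> bool:
        return cell in set(self.cells)


@dataclass
class CommunityPartition:
    """Communities (connected active sets of >= 2 cells) and isolated actives."""

    communities: list[set[int]]
    isolated: set[int]

    def community_of(self) -> dict[int, int]:
        """cell -> community index (isolated cells are absent)."""
        return {c: i for i, comm in enumerate(self.communities) for c in comm}

    @property
    def members(self) -> set[int]:
        return set().union(*self.communities) if self.communities else set()


@dataclass
class CommunityMetrics:
    n_communities: int
    mean_community_size: float
    n_isolated: int
    degree_of_clustering: float
    clustering_coefficient: float
    empty: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "n_communities": self.n_communities,
            "mean_community_size": self.mean_community_size,
            "n_isolated": self.n_isolated,
            "degree_of_clustering": self.degree_of_clustering,
            "clustering_coefficient": self.clustering_coefficient,
        }


@dataclass
class PermutationNull:
    """Observed value vs a label-randomization null distribution."""

    metric: str
    observed: float
    values: np.ndarray
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def percentile(self) -> float:
        """Empirical mid-rank percentile of the observed value in the null."""
        v = np.asarray(self.values, dtype=float)
        below = np.sum(v < self.observed)
        equal = np.sum(v == self.observed)
        return float(100.0 * (below + 0.5 * equal) / v.size)

    def band(self, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
        return tuple(np.percentile(self.values, [lo, hi]))


def select_top_responders(
    summaries: pd.DataFrame,
    tg: TissueGraph,
    fraction: float = 0.20,
    agonist: str = "",
) -> ResponderSet:
    """Top ``fraction`` of interior cells ranked by event frequency.

    Exact size ceil(fraction * n_interior); ties broken by mean amplitude
    (descending) then cell id (ascending) so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    interior = tg.interior
    sub = summaries.loc[summaries.index.intersection(interior)].copy()
    k = int(np.ceil(fraction * len(interior)))
    amp = sub["mean_amplitude"].fillna(0.0)
    sub = sub.assign(_amp=amp, _cid=sub.index.to_numpy()).sort_values(
        by=["frequency", "_amp", "_cid"], ascending=[False, False, True]
    )
    return ResponderSet(agonist=agonist, cells=[int(c) for c in sub.index[:k]])


def find_communities(tg: TissueGraph, responders: ResponderSet) -> CommunityPartition:
    """Connected components of the responder-induced subgraph; singletons are isolated."""
    active = set(responders.cells)
    extra = active - set(tg.interior)
    if extra:
        raise ValueError(f"responders must be interior cells; offending: {sorted(extra)}")
    sub = tg.graph.subgraph(active)
    communities, isolated = [], set()
    for comp in sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c))):
        if len(comp) >= 2:
            communities.append({int(c) for c in comp})
        else:
            isolated.add(int(next(iter(comp))))
    return CommunityPartition(communities=communities, isolated=isolated)


def community_metrics(tg: TissueGraph, partition: CommunityPartition) -> CommunityMetrics:
    """Clustering metrics of community members on the active-induced subgraph.

    ``degree_of_clustering`` is the mean number of active neighbors of a
    community member; the clustering coefficient is the mean local clustering
    coefficient on the same induced subgraph (members with degree < 2
    contribute 0).
    """
    members = partition.members
    active = members | partition.isolated
    if not members:
        return CommunityMetrics(0, 0.0, len(partition.isolated), 0.0, 0.0, empty=True)
    sub = tg.graph.subgraph(active)
    degs = [sub.degree(c) for c in sorted(members)]
    clust = nx.clustering(sub, nodes=sorted(members))
    sizes = [len(c) for c in partition.communities]
    return CommunityMetrics(
        n_communities=len(partition.communities),
        mean_community_size=float(np.mean(sizes)),
        n_isolated=len(partition.isolated),
        degree_of_clustering=float(np.mean(degs)),
        clustering_coefficient=float(np.mean(list(clust.values()))),
    )


def permutation_null(
    tg: TissueGraph,
    n_active: int,
    n_perm: int = 100,
    seed: int = 0,
    observed: CommunityMetrics | None = None,
) -> dict[str, PermutationNull]:
    """Null distributions of community metrics under random activity placement.

    Each permutation draws exactly ``n_active`` interior cells uniformly
    without replacement (activity counts preserved, topology untouched) and
    recomputes every metric.
    """
    interior = tg.interior
    if n_active > len(interior):
        raise ValueError("n_active exceeds the number of interior cells")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_perm):
        cells = [int(c) for c in rng.choice(interior, size=n_active, replace=False)]
        part = find_communities(tg, ResponderSet(agonist="null", cells=cells))
        rows.append(community_metrics(tg, part).as_dict())
    null_df = pd.DataFrame(rows)
    out = {}
    for metric in null_df.columns:
        obs = observed.as_dict()[metric] if observed is not None else np.nan
        out[metric] = PermutationNull(
            metric=metric,
            observed=float(obs),
            values=null_df[metric].to_numpy(dtype=float),
            seed=seed,
        )
    return out
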