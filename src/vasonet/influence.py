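"""Case-control quantification of neighbor influence on Ca2+ event probability.

For every interior target cell, positive cases are target events preceded by
neighbor activity within a window of three times the median FDHM of all
events; negative cases are windows of neighbor activity not followed by a
target response (neighbor events grouped chronologically into non-overlapping
windows, each neighbor counted once per window). P(event | k active
neighbors) is the fraction of positive cases at each neighbor count k, and a
temporal permutation null (event times shuffled across cells with per-cell
counts preserved) probes whether the measured coupling exceeds chance.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .communities import CommunityPartition, PermutationNull
from .graph import TissueGraph

__all__ = [
    "InfluenceCase",
    "InfluenceCurve",
    "compute_window",
    "build_cases",
    "probability_by_k",
    "characteristics_by_k",
    "temporal_permutation",
]


@dataclass
class InfluenceCase:
    target: int
    k: int
    positive: bool
    category: str  # "cluster" | "non-cluster" | "mixed"
    reference_time: float
    event_index: int | None = None  # row in the event table for positive cases


@dataclass
class InfluenceCurve:
    """P(event | k) per neighbor count plus the linear trend."""

    table: pd.DataFrame  # index k, columns positives/negatives/p
    slope: float
    intercept: float
    r2: float


def compute_window(events: pd.DataFrame, multiple: float = 3.0) -> float:
    """Influence window: ``multiple`` x median FDHM of all well-fit events."""
    ok = events[events.fit_ok & np.isfinite(events.fdhm)] if len(events) else events
    if len(ok) == 0:
        raise ValueError("no fitted events to derive the influence window from")
    return float(multiple * ok.fdhm.median())


def _category(
    target: int, neighbor_ids: set[int], community_of: dict[int, int]
) -> str:
    tc = community_of.get(target)
    in_cluster = [tc is not None and community_of.get(nb) == tc for nb in neighbor_ids]
    if all(in_cluster):
        return "cluster"
    if not any(in_cluster):
        return "non-cluster"
    return "mixed"


def build_cases(
    events: pd.DataFrame,
    tg: TissueGraph,
    t_w: float,
    partition: CommunityPartition | None = None,
) -> list[InfluenceCase]:
    """Enumerate positive and negative cases for every interior target cell.

    Positive: one case per target event with k = number of distinct neighbors
    peaking in [t - t_w, t). Negative: neighbor events grouped into
    non-overlapping [t0, t0 + t_w] windows (started at the first ungrouped
    neighbor event); a window is a negative case iff the target has no event
    peak in [t0 - t_w, t0 + t_w]. Windows during which the target responds
    are covered by the positive cases; windows opening immediately after a
    target event are excluded as controls because the target is still inside
    its own transient there (detection cannot resolve a new event within
    roughly one FDHM of the last), so such periods are not at risk.
    """
    community_of = partition.community_of() if partition is not None else {}
    # numpy views per cell: the permutation null rebuilds cases ~100x, so the
    # inner loop must stay free of pandas overhead
    cells = events.cell_id.to_numpy(dtype=int) if len(events) else np.empty(0, dtype=int)
    times = events.peak_time.to_numpy(dtype=float) if len(events) else np.empty(0)
    rows_arr = events.index.to_numpy()
    order0 = np.argsort(times, kind="stable")
    cells, times, rows_arr = cells[order0], times[order0], rows_arr[order0]
    by_cell: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(cells):
        m = cells == c
        by_cell[int(c)] = (times[m], rows_arr[m])
    interior = set(tg.interior)
    cases: list[InfluenceCase] = []
    for target in sorted(interior):
        nbrs = tg.neighbors(target)
        nb_times, nb_ids = [], []
        for nb in nbrs:
            if nb in by_cell:
                t = by_cell[nb][0]
                nb_times.append(t)
                nb_ids.append(np.full(t.size, nb))
        if not nb_times:
            continue
        nb_times = np.concatenate(nb_times)
        order = np.argsort(nb_times, kind="stable")
        nb_times = nb_times[order]
        nb_ids = np.concatenate(nb_ids)[order]
        tgt_times, tgt_rows = by_cell.get(target, (np.empty(0), np.empty(0, dtype=int)))

        # positive cases: one per target event with recent neighbor activity
        for t, row in zip(tgt_times, tgt_rows):
            lo = bisect.bisect_left(nb_times, t - t_w)
            hi = bisect.bisect_left(nb_times, t)
            ids = set(int(i) for i in nb_ids[lo:hi])
            if not ids:
                continue
            cases.append(
                InfluenceCase(
                    target=target,
                    k=len(ids),
                    positive=True,
                    category=_category(target, ids, community_of),
                    reference_time=float(t),
                    event_index=int(row),
                )
            )

        # negative cases: non-overlapping neighbor-activity windows, silent target
        i = 0
        n = nb_times.size
        while i < n:
            t0 = nb_times[i]
            hi = bisect.bisect_right(nb_times, t0 + t_w, lo=i)
            ids = set(int(x) for x in nb_ids[i:hi])
            lo_t = bisect.bisect_left(tgt_times, t0 - t_w)
            hi_t = bisect.bisect_right(tgt_times, t0 + t_w)
            if hi_t == lo_t:  # target silent in and just before the window
                cases.append(
                    InfluenceCase(
                        target=target,
                        k=len(ids),
                        positive=False,
                        category=_category(target, ids, community_of),
                        reference_time=float(t0),
                    )
                )
            i = hi
    return cases


def probability_by_k(
    cases: list[InfluenceCase],
    categories: tuple[str, ...] | None = None,
    k_values: list[int] | None = None,
) -> InfluenceCurve:
    """P(event | k) = positives_k / (positives_k + negatives_k), with a linear fit.

    ``categories`` restricts the cases (e.g. cluster-only); ``k_values``
    restricts to neighbor counts shared across compared datasets.
    """
    if categories is not None:
        cases = [c for c in cases if c.category in categories]
    counts: dict[int, list[int]] = {}
    for c in cases:
        pos, neg = counts.setdefault(c.k, [0, 0])
        counts[c.k] = [pos + int(c.positive), neg + int(not c.positive)]
    rows = []
    for k in sorted(counts):
        if k_values is not None and k not in k_values:
            continue
        pos, neg = counts[k]
        if pos + neg == 0:
            continue
        rows.append((k, pos, neg, pos / (pos + neg)))
    table = pd.DataFrame(rows, columns=["k", "positives", "negatives", "p"]).set_index("k")
    if len(table) >= 2:
        fit = stats.linregress(table.index.to_numpy(dtype=float), table.p.to_numpy())
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    else:
        slope = intercept = r2 = np.nan
    return InfluenceCurve(table=table, slope=slope, intercept=intercept, r2=r2)


def characteristics_by_k(
    cases: list[InfluenceCase], events: pd.DataFrame, by_category: bool = False
) -> pd.DataFrame:
    """Mean event characteristics of positive-case target events, grouped by k."""
    rows = []
    for c in cases:
        if not c.positive or c.event_index is None:
            continue
        ev = events.loc[c.event_index]
        rows.append(
            (c.k, c.category, ev.amplitude, ev.rise_time, ev.fall_time, ev.fdhm)
        )
    df = pd.DataFrame(
        rows, columns=["k", "category", "amplitude", "rise_time", "fall_time", "fdhm"]
    )
    keys = ["k", "category"] if by_category else ["k"]
    return df.groupby(keys).agg(
        n=("amplitude", "size"),
        amplitude=("amplitude", "mean"),
        rise_time=("rise_time", "mean"),
        fall_time=("fall_time", "mean"),
        fdhm=("fdhm", "mean"),
    )


def permute_event_times(
    events: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Shuffle peak times across cells, preserving each cell's event count."""
    out = events.copy()
    times = out.peak_time.to_numpy().copy()
    out["peak_time"] = rng.permutation(times)
    # counts are untouched by construction: rows keep their cell_id
    assert out.groupby("cell_id").size().equals(events.groupby("cell_id").size())
    return out


def temporal_permutation(
    events: pd.DataFrame,
    tg: TissueGraph,
    t_w: float,
    partition: CommunityPartition | None = None,
    n_perm: int = 100,
    seed: int = 0,
    k_values: list[int] | None = None,
) -> dict[str, PermutationNull]:
    """Null P(event | k) and slope under random redistribution of event timing.

    Event peak times are permuted across the network while each cell keeps
    its event count; topology and community labels are untouched. Returns
    one null per shared k (keys ``"p@k"``) plus ``"slope"``.
    """
    rng = np.random.default_rng(seed)
    observed = probability_by_k(build_cases(events, tg, t_w, partition), k_values=k_values)
    ks = list(observed.table.index)
    null_p = {k: np.full(n_perm, np.nan) for k in ks}
    null_slope = np.full(n_perm, np.nan)
    for p in range(n_perm):
        perm = permute_event_times(events, rng)
        curve = probability_by_k(build_cases(perm, tg, t_w, partition), k_values=ks)
        for k in ks:
            if k in curve.table.index:
                null_p[k][p] = curve.table.at[k, "p"]
        null_slope[p] = curve.slope
    out: dict[str, PermutationNull] = {}
    for k in ks:
        vals = null_p[k][np.isfinite(null_p[k])]
        out[f"p@{k}"] = PermutationNull(
            metric=f"p@{k}",
            observed=float(observed.table.at[k, "p"]),
            values=vals,
            seed=seed,
        )
    out["slope"] = PermutationNull(
        metric="slope",
        observed=observed.slope,
        values=null_slope[np.isfinite(null_slope)],
        seed=seed,
    )
    return out
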