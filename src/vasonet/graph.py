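"""Structural cell-adjacency graph from an integer label mask.

Cells in a labeled mask are separated by thin background (membrane gaps);
neighbors are found by expanding every label until the sheet is tiled
(generalized Voronoi assignment of background pixels to the nearest label,
lowest label id on exact ties) and counting 4-connected pixel contacts
between expanded regions. Cells on the edge of the field of view are flagged
via an alpha shape over all cell boundary pixels and excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, find_objects
from scipy.spatial import ConvexHull, Delaunay, QhullError
from skimage.measure import regionprops_table

__all__ = [
    "TissueGraph",
    "expand_labels_nearest",
    "build_adjacency",
    "cell_geometry",
    "mark_boundary_cells",
    "build_tissue_graph",
    "graph_stats",
]


@dataclass
class TissueGraph:
    """Undirected cell-adjacency graph with boundary flags and geometry."""

    graph: nx.Graph
    boundary: set[int] = field(default_factory=set)
    geometry: pd.DataFrame | None = None

    @property
    def interior(self) -> list[int]:
        return sorted(n for n in self.graph.nodes if n not in self.boundary)

    def interior_graph(self) -> nx.Graph:
        return self.graph.subgraph(self.interior).copy()

    def adjacency_matrix(self, nodes: list[int] | None = None) -> np.ndarray:
        nodes = self.interior if nodes is None else nodes
        return nx.to_numpy_array(self.graph, nodelist=nodes, dtype=float)

    def neighbors(self, node: int) -> list[int]:
        return sorted(self.graph.neighbors(node))


def expand_labels_nearest(mask: np.ndarray) -> np.ndarray:
    """Assign every background pixel to the nearest label (lowest id on ties).

    Implemented as a running minimum over per-label Euclidean distance
    transforms; iterating labels in ascending order with strict-< replacement
    makes the lowest label win exact distance ties, so the result is fully
    deterministic and oracle-checkable.
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    best = np.full(mask.shape, np.inf)
    out = np.zeros_like(mask)
    if labels.size == 0:
        return out
    # a label can only win at pixels within the global maximum background
    # distance of its bounding box, so each per-label transform runs on a
    # padded crop; this is exact, not an approximation
    pad = int(np.ceil(distance_transform_edt(mask == 0).max())) + 1
    slices = find_objects(mask)
    h, w = mask.shape
    for lab in labels:
        sl = slices[lab - 1]
        if sl is None:
            continue
        r0 = max(0, sl[0].start - pad)
        r1 = min(h, sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(w, sl[1].stop + pad)
        crop = (slice(r0, r1), slice(c0, c1))
        d = distance_transform_edt(mask[crop] != lab)
        better = d < best[crop]
        out[crop][better] = lab
        best[crop][better] = d[better]
    return out


def _contact_counts(expanded: np.ndarray) -> dict[tuple[int, int], int]:
    """Count 4-connected pixel contacts between distinct expanded regions."""
    pairs = []
    a, b = expanded[:, :-1].ravel(), expanded[:, 1:].ravel()
    m = a != b
    pairs.append(np.stack([a[m], b[m]], axis=1))
    a, b = expanded[:-1, :].ravel(), expanded[1:, :].ravel()
    m = a != b
    pairs.append(np.stack([a[m], b[m]], axis=1))
    allp = np.concatenate(pairs, axis=0)
    if allp.size == 0:
        return {}
    allp = np.sort(allp, axis=1)
    uniq, counts = np.unique(allp, axis=0, return_counts=True)
    return {(int(u), int(v)): int(c) for (u, v), c in zip(uniq, counts)}


def build_adjacency(mask: np.ndarray, contact_min: int = 2) -> nx.Graph:
    """Neighbor graph: expanded regions sharing >= ``contact_min`` pixel contacts.

    The 2-contact default suppresses corner-only artifacts of the pixel grid.
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size < 2:
        g = nx.Graph()
        g.add_nodes_from(int(l) for l in labels)
        return g
    expanded = expand_labels_nearest(mask)
    g = nx.Graph()
    g.add_nodes_from(int(l) for l in labels)
    for (u, v), c in _contact_counts(expanded).items():
        if u > 0 and c >= contact_min:
            g.add_edge(u, v)
    return g


def cell_geometry(mask: np.ndarray) -> pd.DataFrame:
    """Centroid (px), area (px^2) and length/width ratio per cell."""
    props = regionprops_table(
        np.asarray(mask),
        properties=("label", "centroid", "area", "axis_major_length", "axis_minor_length"),
    )
    df = pd.DataFrame(props).rename(
        columns={"centroid-0": "row", "centroid-1": "col", "label": "cell_id"}
    )
    minor = df["axis_minor_length"].replace(0, np.nan)
    df["ratio"] = (df["axis_major_length"] / minor).fillna(1.0).clip(lower=1.0)
    df["equiv_diameter"] = np.sqrt(4.0 * df["area"] / np.pi)
    return df.set_index("cell_id", drop=False)


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    p = points[simplices]  # (n, 3, 2)
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    area2 = np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def _cell_border_pixels(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (row, col) and labels of cell pixels touching background/frame."""
    mask = np.asarray(mask)
    padded = np.pad(mask, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    near_bg = (
        (padded[:-2, 1:-1] == 0)
        | (padded[2:, 1:-1] == 0)
        | (padded[1:-1, :-2] == 0)
        | (padded[1:-1, 2:] == 0)
    )
    sel = (core > 0) & near_bg
    rr, cc = np.nonzero(sel)
    return np.stack([rr, cc], axis=1), core[sel]


def mark_boundary_cells(mask: np.ndarray, alpha: float | None = None) -> set[int]:
    """Flag field-of-view edge cells via an alpha shape of cell boundary pixels.

    A triangle of the Delaunay triangulation is kept when its circumradius is
    below ``alpha`` (default: twice the median equivalent cell diameter); hull
    boundary edges are those on exactly one kept triangle, and a cell is a
    boundary cell when any of its pixels is a vertex of such an edge or
    touches the image frame. If the alpha shape degenerates, the convex hull
    is used with a warning.
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size < 4:
        return {int(l) for l in labels}
    if alpha is None:
        geom = cell_geometry(mask)
        alpha = 2.0 * float(geom["equiv_diameter"].median())

    pts, pt_labels = _cell_border_pixels(mask)
    xy = pts[:, ::-1].astype(float)  # (x=col, y=row)

    boundary: set[int] = set()
    # frame-touching cells are boundary regardless of the hull
    frame = np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
    boundary.update(int(l) for l in np.unique(frame) if l > 0)

    hull_vertex_idx: set[int] = set()
    try:
        tri = Delaunay(xy)
        keep = _circumradii(xy, tri.simplices) < alpha
        kept = tri.simplices[keep]
        if kept.size == 0:
            raise QhullError("alpha shape degenerated: no triangles kept")
        edges = np.concatenate([kept[:, [0, 1]], kept[:, [1, 2]], kept[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        hull_vertex_idx = set(uniq[counts == 1].ravel().tolist())
    except QhullError:
        warnings.warn("alpha shape degenerate; falling back to convex hull", stacklevel=2)
        hull = ConvexHull(xy)
        hull_vertex_idx = set(int(v) for v in hull.vertices)

    boundary.update(int(pt_labels[i]) for i in hull_vertex_idx)
    return boundary


def build_tissue_graph(
    mask: np.ndarray, alpha: float | None = None, contact_min: int = 2
) -> TissueGraph:
    """Adjacency + geometry + boundary flags in one pass over the mask."""
    g = build_adjacency(mask, contact_min=contact_min)
    geom = cell_geometry(mask)
    boundary = mark_boundary_cells(mask, alpha=alpha)
    return TissueGraph(graph=g, boundary=boundary, geometry=geom)


def graph_stats(tg: TissueGraph) -> dict:
    """Mean +/- SEM of neighbor count, area and length/width over interior cells."""
    interior = tg.interior
    if not interior:
        return {"n_interior": 0}
    deg = np.array([tg.graph.degree(n) for n in interior], dtype=float)
    out = {
        "n_interior": len(interior),
        "mean_neighbors": float(deg.mean()),
        "sem_neighbors": float(deg.std(ddof=1) / np.sqrt(deg.size)) if deg.size > 1 else 0.0,
    }
    if tg.geometry is not None:
        sub = tg.geometry.loc[interior]
        for key, col in (("area", "area"), ("ratio", "ratio")):
            x = sub[col].to_numpy(dtype=float)
            out[f"mean_{key}"] = float(x.mean())
            out[f"sem_{key}"] = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return out
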