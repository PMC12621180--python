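import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vasonet.config import SimulationConfig
from vasonet.graph import TissueGraph
from vasonet.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A quick venous sheet: enough cells for network statistics, short record."""
    return SimulationConfig(
        n_cells=80, duration=180.0, render_shape=(288, 288), rng_seed=7,
        concentration=1e-7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, agonists=("ACh", "BK"))


@pytest.fixture(scope="session")
def tissue(small_dataset):
    return small_dataset["tissue"]


def toy_graph(edges, boundary=()):
    """TissueGraph from an explicit edge list, for unit tests."""
    g = nx.Graph()
    g.add_edges_from(edges)
    return TissueGraph(graph=g, boundary=set(boundary))


def block_grid_mask(rows, cols, cell=8, gap=1):
    """Rectangular grid of square cells separated by `gap` background pixels."""
    h = rows * cell + (rows - 1) * gap
    w = cols * cell + (cols - 1) * gap
    mask = np.zeros((h, w), dtype=np.int32)
    lab = 1
    for r in range(rows):
        for c in range(cols):
            r0 = r * (cell + gap)
            c0 = c * (cell + gap)
            mask[r0 : r0 + cell, c0 : c0 + cell] = lab
            lab += 1
    return mask


def event_table(rows):
    """Event DataFrame from (cell_id, peak_time) or full tuples."""
    full = []
    for r in rows:
        if len(r) == 2:
            cid, t = r
            full.append((cid, t, 1.0, 0.5, 1.0, 1.5, True))
        else:
            full.append(r)
    return pd.DataFrame(
        full,
        columns=["cell_id", "peak_time", "amplitude", "rise_time", "fall_time", "fdhm", "fit_ok"],
    )
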