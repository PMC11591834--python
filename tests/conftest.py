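import numpy as np
import pytest

from plvnet.connectivity import PLVMatrix
from plvnet.network import BrainGraph, build_graph
from plvnet.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def graph_from_matrices(adj, weights, labels=None, threshold=0.0):
    n = adj.shape[0]
    labels = labels or tuple(f"n{i}" for i in range(n))
    return BrainGraph(
        adjacency=adj, weights=weights, channel_labels=tuple(labels), threshold=threshold
    )


def graph_from_edges(n, edges, labels=None):
    """edges: iterable of (i, j) or (i, j, weight); weight defaults to 1."""
    adj = np.zeros((n, n), dtype=bool)
    w = np.zeros((n, n))
    for e in edges:
        i, j = e[0], e[1]
        wt = e[2] if len(e) > 2 else 1.0
        adj[i, j] = adj[j, i] = True
        w[i, j] = w[j, i] = wt
    return graph_from_matrices(adj, w, labels)


def plv_from_pairs(labels, pair_values, default=0.0):
    """PLVMatrix from {(i, j): value} over index pairs."""
    n = len(labels)
    v = np.full((n, n), default, dtype=float)
    np.fill_diagonal(v, 1.0)
    for (i, j), val in pair_values.items():
        v[i, j] = v[j, i] = val
    return PLVMatrix(values=v, channel_labels=tuple(labels))


@pytest.fixture
def toy_plv():
    # 4-node example: pairs AB 0.9, AC 0.8, AD 0.4, BC 0.76, BD 0.3, CD 0.2
    return plv_from_pairs(
        ("A", "B", "C", "D"),
        {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.4, (1, 2): 0.76, (1, 3): 0.3, (2, 3): 0.2},
    )


@pytest.fixture
def small_synth_config():
    """Cheap 8-channel config for generator tests."""
    return SynthConfig(
        n_participants=2,
        channel_labels=tuple(f"ch{i}" for i in range(8)),
        duration=24.0,
        jitter_sd={"comfort": 0.8, "fatigue": 0.5},
        noise_sd=1.0,
        seed=7,
    )


@pytest.fixture
def star5():
    """K_{1,5}: node 0 is the hub."""
    return graph_from_edges(6, [(0, i) for i in range(1, 6)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


__all__ = ["graph_from_edges", "graph_from_matrices", "plv_from_pairs", "build_graph"]
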