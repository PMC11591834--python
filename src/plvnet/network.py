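"""Threshold selection and construction of sparse undirected brain graphs."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import PLVMatrix

__all__ = [
    "DEFAULT_THRESHOLD_GRID",
    "BrainGraph",
    "top_fraction_mean",
    "build_graph",
    "sparsity",
    "sparsity_threshold",
    "write_graph",
    "read_graph",
]

#: Threshold grid used for the condition comparison, T_i = 0.72 .. 0.76.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (0.72, 0.73, 0.74, 0.75, 0.76)


@dataclass(frozen=True)
class BrainGraph:
    """Thresholded undirected graph with retained PLV weights."""

    adjacency: np.ndarray  # (C, C) bool, no self-loops
    weights: np.ndarray  # (C, C) float, PLV on present edges, 0 elsewhere
    channel_labels: tuple[str, ...]
    threshold: float
    band: str = ""
    condition: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "weights", w)
        if adj.shape != w.shape or adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency and weights must be matching square matrices")
        if np.any(np.diag(adj)):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(w[~adj] != 0):
            raise ValueError("weights present off the edge set")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int, float]]:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu]
        return [
            (int(i), int(j), float(self.weights[i, j]))
            for i, j in zip(iu[0][mask], iu[1][mask])
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.channel_labels)
        labels = self.channel_labels
        for i, j, w in self.edges():
            g.add_edge(labels[i], labels[j], weight=w)
        return g


def top_fraction_mean(plv: PLVMatrix, fraction: float = 0.20) -> float:
    """Mean of the ``ceil(fraction * n_pairs)`` largest unique-pair PLVs."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    pairs = plv.pair_values()
    if pairs.size == 0:
        raise ValueError("PLV matrix has no off-diagonal pairs")
    k = math.ceil(fraction * pairs.size)
    top = np.sort(pairs)[-k:]
    return float(top.mean())


def build_graph(plv: PLVMatrix, threshold: float) -> BrainGraph:
    """Edge (i, j) present iff PLV_ij >= threshold (ties retained)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    adj = plv.values >= threshold
    np.fill_diagonal(adj, False)
    adj &= adj.T
    weights = np.where(adj, plv.values, 0.0)
    return BrainGraph(
        adjacency=adj,
        weights=weights,
        channel_labels=plv.channel_labels,
        threshold=threshold,
        band=plv.band,
        condition=plv.condition,
        participant=plv.participant,
    )


def sparsity(g: BrainGraph) -> float:
    """Edge count over C(N, 2)."""
    n = g.n_nodes
    possible = n * (n - 1) // 2
    return g.n_edges / possible if possible else 0.0


def sparsity_threshold(plv: PLVMatrix, target: float = 0.20) -> float:
    """Threshold retaining (about) the strongest ``target`` fraction of pairs.

    Returns the value of the ``ceil(target * n_pairs)``-th largest pair PLV;
    applying ``build_graph`` at this threshold keeps at least that many
    edges (more only under ties).
    """
    if not 0 < target <= 1:
        raise ValueError("target sparsity must be in (0, 1]")
    pairs = np.sort(plv.pair_values())[::-1]
    k = math.ceil(target * pairs.size)
    return float(pairs[k - 1])


def write_graph(g: BrainGraph, path: str | Path) -> Path:
    """Edge-list CSV plus a JSON header sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = g.channel_labels
    rows = [
        {"node_a": labels[i], "node_b": labels[j], "weight": w}
        for i, j, w in g.edges()
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(path, index=False)
    header = {
        "channel_labels": list(labels),
        "threshold": g.threshold,
        "band": g.band,
        "condition": g.condition,
        "participant": g.participant,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def read_graph(path: str | Path) -> BrainGraph:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    labels = tuple(header["channel_labels"])
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    adj = np.zeros((n, n), dtype=bool)
    w = np.zeros((n, n))
    df = pd.read_csv(path)
    for _, row in df.iterrows():
        i, j = idx[row["node_a"]], idx[row["node_b"]]
        adj[i, j] = adj[j, i] = True
        w[i, j] = w[j, i] = float(row["weight"])
    return BrainGraph(
        adjacency=adj,
        weights=w,
        channel_labels=labels,
        threshold=float(header["threshold"]),
        band=header.get("band", ""),
        condition=header.get("condition", ""),
        participant=header.get("participant", ""),
    )
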