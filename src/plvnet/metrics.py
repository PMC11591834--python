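"""Graph-theoretic node and edge metrics on thresholded brain networks.

Distances come from a Floyd-Warshall all-pairs pass over one of three edge
length conventions:

- ``binary``: every edge has length 1;
- ``one_minus_w`` (default): length ``1 - PLV``, so strong phase locking
  means a short edge;
- ``inverse_w``: length ``1 / PLV``.

Betweenness centrality uses shortest-path multiplicities obtained by a
per-source dynamic program over nodes in non-decreasing distance order
(correct for strictly positive edge lengths; lengths are clamped to 1e-12
to guard the degenerate PLV == 1 edge). Two path lengths are considered
tied when they differ by less than 1e-10 relative. Local clustering is
evaluated on the binary adjacency. Unreachable pairs contribute zero to
nodal efficiency and are excluded from the characteristic path length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BrainGraph

__all__ = [
    "DistanceMatrix",
    "MetricTable",
    "edge_lengths",
    "floyd_warshall",
    "shortest_paths",
    "betweenness",
    "nodal_efficiency",
    "clustering_local",
    "clustering_global",
    "characteristic_path_length",
    "metrics_for_graph",
]

DISTANCE_MODES = ("binary", "one_minus_w", "inverse_w")
_TIE_RTOL = 1e-10
_MIN_LENGTH = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path lengths and equal-length path multiplicities."""

    d: np.ndarray  # (N, N), np.inf where unreachable, 0 on the diagonal
    path_counts: np.ndarray  # (N, N) float; number of tied shortest paths

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class MetricTable:
    """Per-node (bc, ne, cc_local) and per-graph (cc_global, cpl) metrics."""

    channel_labels: tuple[str, ...]
    bc: np.ndarray
    ne: np.ndarray
    cc_local: np.ndarray
    cc_global: float
    cpl: float
    threshold: float = float("nan")
    band: str = ""
    condition: str = ""
    participant: str = ""
    distance_mode: str = "one_minus_w"

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per node-metric plus GLOBAL rows."""
        rows = []
        meta = {
            "participant": self.participant,
            "condition": self.condition,
            "band": self.band,
            "threshold": self.threshold,
        }
        for metric, values in (("bc", self.bc), ("ne", self.ne), ("cc", self.cc_local)):
            for label, v in zip(self.channel_labels, values):
                rows.append({**meta, "node": label, "metric": metric, "value": v})
        rows.append({**meta, "node": "GLOBAL", "metric": "cc_global", "value": self.cc_global})
        rows.append({**meta, "node": "GLOBAL", "metric": "cpl", "value": self.cpl})
        return pd.DataFrame(rows)


def _tied(a: float, b: float) -> bool:
    return abs(a - b) <= _TIE_RTOL * max(1.0, abs(a), abs(b))


def edge_lengths(g: BrainGraph, distance_mode: str = "one_minus_w") -> np.ndarray:
    """(N, N) matrix of edge lengths, np.inf where no edge."""
    if distance_mode not in DISTANCE_MODES:
        raise ValueError(f"distance_mode must be one of {DISTANCE_MODES}")
    n = g.n_nodes
    lengths = np.full((n, n), np.inf)
    adj = g.adjacency
    if distance_mode == "binary":
        lengths[adj] = 1.0
    elif distance_mode == "one_minus_w":
        lengths[adj] = np.maximum(1.0 - g.weights[adj], _MIN_LENGTH)
    else:
        with np.errstate(divide="ignore"):
            inv = 1.0 / g.weights[adj]
        lengths[adj] = np.where(np.isfinite(inv), inv, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by the Floyd-Warshall recursion."""
    d = lengths.copy()
    n = d.shape[0]
    for k in range(n):
        via = d[:, k : k + 1] + d[k : k + 1, :]
        np.minimum(d, via, out=d)
    return d


def _count_paths(lengths: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Shortest-path multiplicities per source by distance-ordered DP."""
    n = d.shape[0]
    counts = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s], kind="stable")
        sigma = np.zeros(n)
        sigma[s] = 1.0
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            preds = 0.0
            for u in range(n):
                luv = lengths[u, v]
                if u != v and np.isfinite(luv) and np.isfinite(d[s, u]):
                    if _tied(d[s, u] + luv, d[s, v]):
                        preds += sigma[u]
            sigma[v] = preds
        counts[s] = sigma
    np.fill_diagonal(counts, 1.0)
    return counts


def shortest_paths(g: BrainGraph, distance_mode: str = "one_minus_w") -> DistanceMatrix:
    """Distances and shortest-path multiplicities for all node pairs."""
    lengths = edge_lengths(g, distance_mode)
    d = floyd_warshall(lengths)
    counts = _count_paths(lengths, d)
    return DistanceMatrix(d=d, path_counts=counts)


def betweenness(
    g: BrainGraph, dm: DistanceMatrix, distance_mode: str = "one_minus_w"
) -> np.ndarray:
    """Normalized betweenness centrality per node.

    ``c_B(j) = sum over pairs s < t (both != j) of sigma_st(j) / sigma_st``,
    divided by ``(N - 1)(N - 2) / 2``; endpoints are excluded. Pairs with no
    path contribute nothing.
    """
    n = dm.n
    if n < 3:
        import warnings

        warnings.warn("betweenness undefined for N < 3; returning zeros")
        return np.zeros(n)
    lengths = edge_lengths(g, distance_mode)
    d, sigma = dm.d, dm.path_counts
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for j in range(n):
                if j == s or j == t:
                    continue
                if (
                    np.isfinite(d[s, j])
                    and np.isfinite(d[j, t])
                    and _tied(d[s, j] + d[j, t], d[s, t])
                ):
                    bc[j] += sigma[s, j] * sigma[j, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm


def nodal_efficiency(dm: DistanceMatrix) -> np.ndarray:
    """Mean inverse shortest-path distance from each node to all others.

    Unreachable targets contribute zero. In binary mode this lies in
    [0, 1]; with sub-unit weighted distances it may exceed 1 and is
    reported unclamped.
    """
    n = dm.n
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    d = dm.d.copy()
    np.fill_diagonal(d, np.inf)  # exclude self-distance
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    return inv.sum(axis=1) / (n - 1)


def clustering_local(g: BrainGraph) -> np.ndarray:
    """Binary local clustering coefficient, 0 for nodes of degree < 2."""
    adj = g.adjacency.astype(int)
    deg = adj.sum(axis=1)
    # diagonal of A^3 counts closed triangles through each node (x2)
    tri = np.diag(adj @ adj @ adj) / 2.0
    cc = np.zeros(g.n_nodes)
    mask = deg >= 2
    cc[mask] = 2.0 * tri[mask] / (deg[mask] * (deg[mask] - 1))
    return cc


def clustering_global(cc_locals: np.ndarray) -> float:
    """Arithmetic mean of local clustering coefficients over all nodes."""
    cc_locals = np.asarray(cc_locals, dtype=float)
    if cc_locals.size == 0:
        raise ValueError("no nodes")
    return float(cc_locals.mean())


def characteristic_path_length(dm: DistanceMatrix) -> float:
    """Mean finite off-diagonal shortest-path length.

    Self-distances and unreachable pairs are excluded; raises if no pair
    is connected at all.
    """
    d = dm.d.copy()
    np.fill_diagonal(d, np.inf)
    finite = d[np.isfinite(d)]
    if finite.size == 0:
        raise ValueError("graph has no connected node pair; CPL undefined")
    return float(finite.mean())


def metrics_for_graph(
    g: BrainGraph,
    distance_mode: str = "one_minus_w",
    on_disconnected: str = "raise",
) -> MetricTable:
    """All five metric families from a single distance computation.

    ``on_disconnected="nan"`` reports NaN CPL instead of raising when the
    graph has no connected pair (useful in batch pipelines where extreme
    thresholds can empty a participant's graph).
    """
    dm = shortest_paths(g, distance_mode)
    bc = betweenness(g, dm, distance_mode) if g.n_nodes >= 3 else np.zeros(g.n_nodes)
    ne = nodal_efficiency(dm)
    cc = clustering_local(g)
    try:
        cpl = characteristic_path_length(dm)
    except ValueError:
        if on_disconnected == "nan":
            cpl = float("nan")
        else:
            raise
    return MetricTable(
        channel_labels=g.channel_labels,
        bc=bc,
        ne=ne,
        cc_local=cc,
        cc_global=clustering_global(cc),
        cpl=cpl,
        threshold=g.threshold,
        band=g.band,
        condition=g.condition,
        participant=g.participant,
        distance_mode=distance_mode,
    )
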