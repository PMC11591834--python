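"""Independent brute-force oracle for graph metrics on small graphs.

Shortest paths are found by exhaustively enumerating every simple path
between every node pair (all permutations of intermediate nodes), then the
metric formulas are evaluated directly from the enumeration. Written before
and kept independent of the package implementation.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

TIE_RTOL = 1e-10


def _tied(a: float, b: float) -> bool:
    return abs(a - b) <= TIE_RTOL * max(1.0, abs(a), abs(b))


@lru_cache(maxsize=None)
def _perm_table(n_rest: int) -> np.ndarray:
    """All ordered selections of 0..n_rest intermediates, padded with -1."""
    rows = []
    for k in range(n_rest + 1):
        for perm in itertools.permutations(range(n_rest), k):
            rows.append(list(perm) + [-1] * (n_rest - k))
    return np.asarray(rows, dtype=np.int64)


def enumerate_pair(lengths: np.ndarray, s: int, t: int):
    """(min length, #tied shortest, per-node traversal counts) for pair s-t."""
    n = lengths.shape[0]
    rest = np.asarray([v for v in range(n) if v not in (s, t)], dtype=np.int64)
    tmpl = _perm_table(len(rest))
    mid = np.where(tmpl >= 0, rest[np.clip(tmpl, 0, None)], t)  # pad with t
    seq = np.empty((tmpl.shape[0], tmpl.shape[1] + 2), dtype=np.int64)
    seq[:, 0] = s
    seq[:, 1:-1] = mid
    seq[:, -1] = t
    plen = lengths[seq[:, :-1], seq[:, 1:]].sum(axis=1)  # t->t edges add 0
    finite = np.isfinite(plen)
    if not finite.any():
        return np.inf, 0.0, np.zeros(n)
    best = plen[finite].min()
    tied = finite & (np.abs(plen - best) <= TIE_RTOL * np.maximum(1.0, np.abs(best)))
    through = np.zeros(n)
    inner = seq[tied][:, 1:-1]
    for j in rest:
        through[j] = float((inner == j).any(axis=1).sum())
    return float(best), float(tied.sum()), through


def all_pairs(lengths: np.ndarray):
    """Exhaustive distances, shortest-path counts, and through-node counts."""
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    through = np.zeros((n, n, n))
    for s in range(n):
        for t in range(s + 1, n):
            dist, cnt, thr = enumerate_pair(lengths, s, t)
            d[s, t] = d[t, s] = dist
            counts[s, t] = counts[t, s] = cnt
            through[s, t] = through[t, s] = thr
    return d, counts, through


def lengths_from(adj: np.ndarray, weights: np.ndarray | None, mode: str) -> np.ndarray:
    n = adj.shape[0]
    lengths = np.full((n, n), np.inf)
    if mode == "binary":
        lengths[adj] = 1.0
    elif mode == "one_minus_w":
        lengths[adj] = 1.0 - weights[adj]
    elif mode == "inverse_w":
        lengths[adj] = 1.0 / weights[adj]
    else:
        raise ValueError(mode)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def betweenness_direct(d, counts, through) -> np.ndarray:
    n = d.shape[0]
    bc = np.zeros(n)
    for j in range(n):
        total = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if j in (s, t) or not np.isfinite(d[s, t]) or counts[s, t] == 0:
                    continue
                total += through[s, t, j] / counts[s, t]
        bc[j] = total
    return bc / ((n - 1) * (n - 2) / 2.0)


def nodal_efficiency_direct(d) -> np.ndarray:
    n = d.shape[0]
    ne = np.zeros(n)
    for j in range(n):
        acc = 0.0
        for k in range(n):
            if k != j and np.isfinite(d[j, k]) and d[j, k] > 0:
                acc += 1.0 / d[j, k]
        ne[j] = acc / (n - 1)
    return ne


def clustering_direct(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    cc = np.zeros(n)
    for i in range(n):
        nbrs = [k for k in range(n) if adj[i, k]]
        k_i = len(nbrs)
        if k_i < 2:
            continue
        e_i = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        cc[i] = 2.0 * e_i / (k_i * (k_i - 1))
    return cc


def cpl_direct(d) -> float:
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    if not vals:
        raise ValueError("fully disconnected")
    return float(np.mean(vals))


def random_graph(rng: np.random.Generator, n: int, density: float, weighted: bool):
    """Random symmetric graph; weights in [0.6, 0.99] when weighted."""
    adj = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    adj[iu[0][mask], iu[1][mask]] = True
    adj |= adj.T
    w = np.zeros((n, n))
    if weighted:
        vals = rng.uniform(0.6, 0.99, len(iu[0]))
        w[iu] = vals
        w = w + w.T
    else:
        w[adj] = 1.0
    w[~adj] = 0.0
    return adj, w
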