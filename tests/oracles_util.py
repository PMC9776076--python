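"""Independent brute-force oracles for the graph metrics.

These deliberately avoid the package's own algorithms: distances come from
Floyd-Warshall (scipy), betweenness from exhaustive simple-path
enumeration, clustering/transitivity from direct triple loops.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import floyd_warshall

TIE = 1e-10


def lengths_of(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = 1.0 / np.asarray(w, dtype=float)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def fw_distances(w: np.ndarray) -> np.ndarray:
    lengths = lengths_of(w)
    graph = np.where(np.isfinite(lengths), lengths, 0.0)
    mask = np.isfinite(lengths) & (lengths > 0)
    return floyd_warshall(np.where(mask, graph, 0.0), directed=False)


def cpl_oracle(w: np.ndarray) -> float:
    d = fw_distances(w)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(d[off].reshape(n, n - 1).mean(axis=1).mean())


def ge_oracle(w: np.ndarray) -> float:
    d = fw_distances(w)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def _all_simple_paths(w: np.ndarray, s: int, t: int):
    """Yield (length, interior-nodes) of every simple path s -> t."""
    n = w.shape[0]
    lengths = lengths_of(w)
    stack = [(s, 0.0, (s,))]
    while stack:
        node, acc, path = stack.pop()
        for nxt in range(n):
            if w[node, nxt] <= 0 or nxt in path:
                continue
            nacc = acc + lengths[node, nxt]
            if nxt == t:
                yield nacc, path[1:]
            else:
                stack.append((nxt, nacc, path + (nxt,)))


def betweenness_oracle(w: np.ndarray) -> np.ndarray:
    """Exhaustive-enumeration betweenness with the 2/((N-1)(N-2)) scale."""
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = list(_all_simple_paths(w, s, t))
            if not paths:
                continue
            dmin = min(p[0] for p in paths)
            shortest = [p for p in paths
                        if p[0] <= dmin + TIE * max(dmin, 1.0)]
            n_st = len(shortest)
            for _, interior in shortest:
                for v in interior:
                    bc[v] += 1.0 / n_st
    return 2.0 * bc / ((n - 1) * (n - 2))


def clustering_oracle(w: np.ndarray, mode: str) -> np.ndarray:
    n = w.shape[0]
    a = (w > 0).astype(float)
    w_hat = w / w.max() if w.max() > 0 else w
    cc = np.zeros(n)
    for i in range(n):
        k = a[i].sum()
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                if mode == "binary":
                    t += a[i, j] * a[i, h] * a[j, h]
                else:
                    t += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        cc[i] = t / (k * (k - 1))
    return cc


def transitivity_oracle(w: np.ndarray, mode: str) -> float:
    n = w.shape[0]
    a = (w > 0).astype(float)
    w_hat = w / w.max() if w.max() > 0 else w
    num = 0.0
    den = 0.0
    for i in range(n):
        k = a[i].sum()
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                if mode == "binary":
                    num += a[i, j] * a[i, h] * a[j, h]
                else:
                    num += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
    return num / den if den > 0 else 0.0


def random_weighted_graph(rng: np.random.Generator, n: int,
                          p_edge: float = 0.7) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = rng.uniform(0.2, 1.0, size=(n, n))
    mask = rng.random((n, n)) < p_edge
    w = np.triu(w * mask, k=1)
    return w + w.T
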