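"""Weighted small-world graph metrics on connectivity matrices.

Five metrics characterize integration and segregation of a weighted
undirected network with nonnegative edge weights (0 = no edge):

* betweenness centrality   BC_i = 2/((N-1)(N-2)) * sum_{h!=j!=i} n_hj(i)/n_hj
* characteristic path length  L = (1/N) sum_i l_i,  l_i = mean_j l_ij
* global efficiency        GE = 1/(N(N-1)) * sum_{i!=j} 1/l_ij
* clustering coefficient   CC_i = 2 t_i / (k_i (k_i - 1))
* transitivity             t = sum_i t_i / m,  m = sum_i k_i(k_i-1)/2

Path metrics map weights to lengths reciprocally (l = 1/w: stronger
coupling = shorter path) and use Dijkstra with shortest-path multiplicity
counting; two path lengths count as equal when they differ by at most a
1e-10 relative tolerance. Disconnected node pairs have infinite distance:
the characteristic path length is then infinite (flagged), while global
efficiency uses the 1/inf = 0 convention and stays finite.

Triangle metrics come in a ``binary`` mode (edge counts, the printed form of
the equations) and a ``weighted`` mode using the Onnela geometric-mean
triangle intensity t_i = 1/2 sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) on weights
rescaled by the network maximum, with the same degree-based denominator.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

#: Relative tolerance under which two path lengths are the same path length.
PATH_TIE_RTOL = 1e-10


@dataclass(frozen=True)
class GraphContext:
    """A weighted undirected graph given by its nonnegative weight matrix."""

    weights: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"n{i}" for i in range(w.shape[0])))

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        """Reciprocal weight-to-length map: 1/w for w > 0, inf otherwise."""
        with np.errstate(divide="ignore"):
            lengths = 1.0 / self.weights
        return lengths


@dataclass(frozen=True)
class ShortestPathResult:
    """All-pairs shortest-path lengths and path multiplicities."""

    dist: np.ndarray     # l_ij, inf for disconnected pairs
    sigma: np.ndarray    # number of shortest paths n_ij, 0 for disconnected


@dataclass(frozen=True)
class GraphMetricsResult:
    """Per-node and global small-world metrics for one network."""

    labels: tuple[str, ...]
    bc: np.ndarray
    cc: np.ndarray
    cpl: float
    ge: float
    transitivity: float
    mode: str
    degree: np.ndarray
    strength: np.ndarray
    connected: bool


def _sssp(lengths: np.ndarray, adj: list[np.ndarray], s: int):
    """Dijkstra from ``s`` with path counting and predecessor lists.

    Returns (order of settlement, dist, sigma, predecessor lists).
    """
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    preds: list[list[int]] = [[] for _ in range(n)]
    done = np.zeros(n, dtype=bool)
    dist[s] = 0.0
    sigma[s] = 1.0
    heap: list[tuple[float, int]] = [(0.0, s)]
    order: list[int] = []
    tol = PATH_TIE_RTOL
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        order.append(u)
        du = dist[u]
        row = lengths[u]
        for v in adj[u]:
            if done[v]:
                continue
            nd = du + row[v]
            dv = dist[v]
            # tie iff |nd - dv| <= rtol * max(nd, dv), both finite
            tied = dv != np.inf and abs(nd - dv) <= tol * (nd if nd > dv
                                                           else dv)
            if nd < dv and not tied:
                dist[v] = nd
                sigma[v] = sigma[u]
                preds[v] = [u]
                heapq.heappush(heap, (nd, v))
            elif tied:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return order, dist, sigma, preds


def shortest_paths(g: GraphContext) -> ShortestPathResult:
    """All-pairs shortest paths on reciprocal edge lengths."""
    lengths = g.lengths
    adj = [np.flatnonzero(np.isfinite(lengths[i]) & (np.arange(g.n) != i))
           for i in range(g.n)]
    dist = np.empty((g.n, g.n))
    sigma = np.empty((g.n, g.n))
    for s in range(g.n):
        _, d, sg, _ = _sssp(lengths, adj, s)
        dist[s] = d
        sigma[s] = sg
    np.fill_diagonal(sigma, 0.0)
    return ShortestPathResult(dist=dist, sigma=sigma)


def _brandes(g: GraphContext) -> tuple[np.ndarray, np.ndarray]:
    """Betweenness and the all-pairs distance matrix in one sweep."""
    n = g.n
    lengths = g.lengths
    adj = [np.flatnonzero(np.isfinite(lengths[i]) & (np.arange(n) != i))
           for i in range(n)]
    bc = np.zeros(n)
    dist_all = np.empty((n, n))
    for s in range(n):
        order, dist, sigma, preds = _sssp(lengths, adj, s)
        dist_all[s] = dist
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was visited from both endpoints
    return bc / ((n - 1) * (n - 2)), dist_all


def betweenness(g: GraphContext) -> np.ndarray:
    """Betweenness centrality of every node, normalized to [0, 1].

    Brandes' dependency accumulation over weighted shortest paths; the
    normalization 2/((N-1)(N-2)) over unordered pairs puts the center of a
    star at exactly 1.
    """
    if g.n < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    return _brandes(g)[0]


def char_path_length(g: GraphContext,
                     dist: np.ndarray | None = None) -> float:
    """Characteristic path length L; infinite if any pair is disconnected."""
    if g.n < 2:
        raise ValueError("need at least 2 nodes")
    if dist is None:
        dist = shortest_paths(g).dist
    off = ~np.eye(g.n, dtype=bool)
    l_i = dist[off].reshape(g.n, g.n - 1).mean(axis=1)
    return float(l_i.mean())


def global_efficiency(g: GraphContext,
                      dist: np.ndarray | None = None) -> float:
    """Global efficiency; disconnected pairs contribute zero."""
    if g.n < 2:
        raise ValueError("need at least 2 nodes")
    if dist is None:
        dist = shortest_paths(g).dist
    off = ~np.eye(g.n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def _triangle_intensity(g: GraphContext, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-node triangle term t_i and degree k_i for the chosen mode."""
    a = (g.weights > 0).astype(float)
    k = a.sum(axis=1)
    if mode == "binary":
        t = np.diag(a @ a @ a) / 2.0
    elif mode == "weighted":
        peak = g.weights.max()
        w_hat = g.weights / peak if peak > 0 else g.weights
        cube = np.cbrt(w_hat)
        t = np.diag(cube @ cube @ cube) / 2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return t, k


def clustering_coef(g: GraphContext, mode: str = "weighted") -> np.ndarray:
    """Per-node clustering coefficient CC_i; 0 where the degree is < 2."""
    t, k = _triangle_intensity(g, mode)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return cc


def transitivity(g: GraphContext, mode: str = "weighted") -> float:
    """Global triangle-to-triple ratio; 0 when the network has no triples."""
    t, k = _triangle_intensity(g, mode)
    m = (k * (k - 1)).sum() / 2.0
    return float(t.sum() / m) if m > 0 else 0.0


def graph_metrics(weights: np.ndarray,
                  labels: tuple[str, ...] | None = None,
                  mode: str = "weighted") -> GraphMetricsResult:
    """All five small-world metrics of one connectivity matrix."""
    g = GraphContext(weights=weights, labels=labels)
    if g.n < 3:
        raise ValueError("graph metrics need at least 3 nodes")
    bc, dist = _brandes(g)
    connected = bool(np.isfinite(dist).all())
    a = (g.weights > 0)
    return GraphMetricsResult(
        labels=g.labels,
        bc=bc,
        cc=clustering_coef(g, mode),
        cpl=char_path_length(g, dist),
        ge=global_efficiency(g, dist),
        transitivity=transitivity(g, mode),
        mode=mode,
        degree=a.sum(axis=1).astype(float),
        strength=g.weights.sum(axis=1),
        connected=connected,
    )
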