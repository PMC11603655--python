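"""Thresholded inter-regional correlation graphs and node metrics.

Region z-scores are averaged over one-second blocks, pairwise Pearson
correlations computed, and an unweighted graph built with an edge wherever
|r| >= threshold (default 0.8).  Five node metrics are computed from first
principles on the boolean adjacency: degree, clustering coefficient, local
efficiency, betweenness centrality (Brandes' algorithm, normalized by
(n-1)(n-2)/2) and closeness centrality (Wasserman-Faust scaling for
disconnected graphs).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import RegionTraces
from .stats import friedman_dunn_table

METRICS: tuple[str, ...] = ("degree", "clustering", "local_efficiency", "betweenness", "closeness")
DEFAULT_THRESHOLD = 0.8


def coarse_average(traces: RegionTraces | np.ndarray, fps: float | None = None, window_s: float = 1.0) -> np.ndarray:
    """Non-overlapping block means over ``window_s``-second windows.

    Blocks are delimited by time boundaries (frame floor(b * fps * window_s)),
    so a 600-s session at 11.7 fps yields exactly 600 one-second blocks of 11
    or 12 frames.  Accepts a RegionTraces (fps taken from it) or a (regions,
    frames) array with explicit fps.  The final short block is averaged over
    the frames it has.  Returns (regions, n_blocks).
    """
    if isinstance(traces, RegionTraces):
        values, fps = traces.values, traces.fps
    else:
        values = np.asarray(traces, dtype=float)
        if fps is None:
            raise ValueError("fps required for plain arrays")
    n = values.shape[1]
    block_f = fps * window_s  # frames per block, generally non-integer
    n_blocks = int(np.ceil(n / block_f - 1e-9))
    bounds = np.minimum(np.floor(np.arange(n_blocks + 1) * block_f).astype(int), n)
    out = np.empty((values.shape[0], n_blocks))
    for b in range(n_blocks):
        out[:, b] = values[:, bounds[b] : max(bounds[b + 1], bounds[b] + 1)].mean(axis=1)
    return out


def correlation_matrix(blocks: np.ndarray, region_names=None) -> np.ndarray:
    """Pairwise Pearson correlation of the block matrix (rows = regions)."""
    blocks = np.asarray(blocks, dtype=float)
    if blocks.shape[1] < 3:
        raise ValueError("need at least 3 blocks")
    sd = blocks.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        names = [region_names[i] if region_names else str(i) for i in bad]
        raise ValueError(f"zero-variance region(s): {names}")
    return np.corrcoef(blocks)


@dataclass
class CorrelationGraph:
    """12x12 correlation matrix plus boolean adjacency at a stated threshold."""

    corr: np.ndarray
    adjacency: np.ndarray
    threshold: float
    node_names: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def possible_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def edge_fraction(self) -> float:
        return self.edge_count / self.possible_edges


def threshold_graph(
    corr: np.ndarray, threshold: float = DEFAULT_THRESHOLD, node_names=None
) -> CorrelationGraph:
    """Boolean adjacency where |r| >= threshold (absolute-value rule), no self-loops."""
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("corr must be a symmetric square matrix")
    adj = np.abs(corr) >= threshold
    np.fill_diagonal(adj, False)
    names = tuple(node_names) if node_names is not None else tuple(str(i) for i in range(n))
    return CorrelationGraph(corr=corr, adjacency=adj, threshold=threshold, node_names=names)


# ----------------------------------------------------------------- node metrics


def _bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    q = deque([source])
    while q:
        v = q.popleft()
        for w in np.flatnonzero(adj[v]):
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def _degree(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1).astype(float)


def _clustering(adj: np.ndarray) -> np.ndarray:
    """2 * triangles / (k (k-1)); zero for nodes of degree < 2."""
    n = adj.shape[0]
    out = np.zeros(n)
    a = adj.astype(int)
    triangles = np.diag(a @ a @ a) / 2.0
    k = _degree(adj)
    mask = k >= 2
    out[mask] = 2.0 * triangles[mask] / (k[mask] * (k[mask] - 1.0))
    return out


def _local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Mean inverse shortest-path length among each node's neighbors, within the
    subgraph induced by those neighbors; zero for degree < 2."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total = 0.0
        for s in range(k):
            d = _bfs_distances(sub, s)
            reach = (d > 0)
            total += (1.0 / d[reach]).sum()
        out[i] = total / (k * (k - 1))
    return out


def _betweenness(adj: np.ndarray) -> np.ndarray:
    """Brandes' accumulation; endpoints excluded; normalized by (n-1)(n-2)/2."""
    n = adj.shape[0]
    bc = np.zeros(n)
    neighbors = [np.flatnonzero(adj[v]) for v in range(n)]
    for s in range(n):
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            stack.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if n > 2:
        bc /= (n - 1) * (n - 2)  # undirected: counts each pair twice, so this is /2 per pair
    return bc


def _closeness(adj: np.ndarray) -> np.ndarray:
    """Wasserman-Faust closeness: ((R-1)/(n-1)) * (R-1)/sum(d) over the node's
    reachable set of size R; zero for isolated nodes."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        d = _bfs_distances(adj, i)
        reach = d > 0
        r = int(reach.sum()) + 1
        if r <= 1:
            continue
        total = float(d[reach].sum())
        out[i] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def node_metrics(graph: CorrelationGraph | np.ndarray) -> pd.DataFrame:
    """All five node metrics of the boolean adjacency, one row per node."""
    if isinstance(graph, CorrelationGraph):
        adj, names = graph.adjacency, graph.node_names
    else:
        adj = np.asarray(graph, dtype=bool)
        names = tuple(str(i) for i in range(adj.shape[0]))
    adj = adj.astype(bool)
    if adj.shape[0] != adj.shape[1] or not (adj == adj.T).all() or adj.diagonal().any():
        raise ValueError("adjacency must be symmetric, boolean and irreflexive")
    return pd.DataFrame(
        {
            "node": list(names),
            "degree": _degree(adj),
            "clustering": _clustering(adj),
            "local_efficiency": _local_efficiency(adj),
            "betweenness": _betweenness(adj),
            "closeness": _closeness(adj),
        }
    )


def session_graph(traces: RegionTraces, threshold: float = DEFAULT_THRESHOLD, window_s: float = 1.0) -> CorrelationGraph:
    """1-s block averaging of z-scored traces -> Pearson matrix -> thresholded graph."""
    values = traces.values
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance region trace")
    blocks = coarse_average((values - mu) / sd, fps=traces.fps, window_s=window_s)
    corr = correlation_matrix(blocks, region_names=traces.region_names)
    return threshold_graph(corr, threshold=threshold, node_names=traces.region_names)


def group_compare(metrics_long: pd.DataFrame, reference: str = "saline") -> pd.DataFrame:
    """Friedman + Dunn (drug vs reference) per region per metric.

    ``metrics_long`` columns: subject, condition, region, metric, value, with a
    complete subjects x conditions cell for every (region, metric).
    """
    return friedman_dunn_table(
        metrics_long, value="value", group_by=["region", "metric"], reference=reference
    )
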