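"""Node centrality indices for weighted symptom networks.

Four indices are computed per node i:

* strength          sum_j |w_ij|
* expected influence sum_j w_ij   (signed, one-step)
* closeness         (p-1) / sum_j dist(i, j), with edge length 1/|w_ij|
* betweenness       Freeman betweenness on the same distance graph, with
                    fractional credit among tied shortest paths

Zero-weight pairs are non-edges (infinite distance); a node that cannot
reach every other node gets closeness 0.  Standardized tables use the
sample standard deviation (n-1 denominator); a constant index maps to
all-zero z-scores.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .datasets import ValidationError
from .network import Network

__all__ = [
    "strength",
    "expected_influence",
    "closeness",
    "betweenness",
    "centrality_table",
    "standardize",
]

INDICES = ("strength", "expected_influence", "closeness", "betweenness")


def _distance_matrix(network: Network) -> np.ndarray:
    with np.errstate(divide="ignore"):
        d = 1.0 / np.abs(network.weights)
    np.fill_diagonal(d, 0.0)
    return d


def strength(network: Network, node: str) -> float:
    """Absolute sum of the node's edge weights."""
    i = network.index(node)
    return float(np.abs(network.weights[i]).sum())


def expected_influence(network: Network, node: str) -> float:
    """Signed sum of the node's edge weights (one-step expected influence)."""
    i = network.index(node)
    return float(network.weights[i].sum())


def _all_closeness(network: Network) -> np.ndarray:
    p = network.n_nodes
    if p < 2:
        return np.zeros(p)
    dist = dijkstra(_distance_matrix(network), directed=False)
    out = np.zeros(p)
    for i in range(p):
        row = np.delete(dist[i], i)
        if np.isinf(row).any():
            out[i] = 0.0
        else:
            out[i] = (p - 1) / row.sum()
    return out


def closeness(network: Network, node: str) -> float:
    """Inverse mean shortest-path distance to all other nodes (0 if any
    node is unreachable)."""
    return float(_all_closeness(network)[network.index(node)])


def _all_betweenness(network: Network) -> np.ndarray:
    """Brandes' algorithm on the 1/|w| distance graph, undirected, with each
    unordered pair counted once."""
    p = network.n_nodes
    d = _distance_matrix(network)
    adj = [np.flatnonzero((network.weights[i] != 0.0)) for i in range(p)]
    bc = np.zeros(p)
    for s in range(p):
        # single-source Dijkstra with path counting
        dist = np.full(p, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(p)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(p)]
        done = np.zeros(p, dtype=bool)
        order: list[int] = []
        for _ in range(p):
            cand = np.where(~done, dist, np.inf)
            v = int(np.argmin(cand))
            if np.isinf(cand[v]):
                break
            done[v] = True
            order.append(v)
            for w in adj[v]:
                alt = dist[v] + d[v, w]
                if alt < dist[w] - 1e-15:
                    dist[w] = alt
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                elif abs(alt - dist[w]) <= 1e-15 and v != w and not done[w]:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(p)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered (s, t) pair was visited twice


def betweenness(network: Network, node: str) -> float:
    """Number of shortest paths between other node pairs passing through the
    node, with ties splitting credit fractionally."""
    return float(_all_betweenness(network)[network.index(node)])


def centrality_table(network: Network) -> pd.DataFrame:
    """All four centrality indices for every node (raw values)."""
    w = network.weights
    df = pd.DataFrame(
        {
            "strength": np.abs(w).sum(axis=1),
            "expected_influence": w.sum(axis=1),
            "closeness": _all_closeness(network),
            "betweenness": _all_betweenness(network),
        },
        index=list(network.labels),
    )
    df.index.name = "node"
    return df


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-index z-scores using the sample SD; constant columns map to 0."""
    if len(table) < 2:
        raise ValidationError("standardization needs at least two nodes")
    z = table.copy().astype(float)
    for col in z.columns:
        sd = z[col].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            z[col] = 0.0
        else:
            z[col] = (z[col] - z[col].mean()) / sd
    return z
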