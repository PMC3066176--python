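"""Per-residue network topological parameters.

Eight centrality-style measures describe each residue's position in the
contact network: degree, clustering coefficient, hub score, cocitation,
coreness, Burt constraint, betweenness and closeness.

Conventions (pinned because downstream keyAA selection depends on them):

* closeness: ``(r - 1) / sum_d`` over reachable vertices only, where ``r``
  counts the reachable component including the vertex itself; isolated
  vertices score 0.  Bounded in [0, 1].
* betweenness: raw Brandes pair counts, unordered pairs counted once,
  unnormalized.
* hub score: Perron eigenvector of the adjacency matrix, rescaled to
  max 1 (on an undirected graph HITS hubs equal eigenvector centrality).
* cocitation: row sum of the cocitation matrix |N(v) ∩ N(u)| over u ≠ v.
* clustering: 0 for degree < 2 so feature vectors stay numeric.
* constraint: Burt's measure with p = 1/degree; isolated vertices score 0.
"""

from __future__ import annotations

from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd

from catres.contact_network import ContactNetwork

#: fixed column order of the network-parameter block
CENTRALITY_NAMES = [
    "degree", "clustering", "hub_score", "cocitation",
    "coreness", "constraint", "betweenness", "closeness",
]


def degree(network: ContactNetwork, v: Hashable) -> int:
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    return network.graph.degree(v)


def clustering_coefficient(network: ContactNetwork, v: Hashable) -> float:
    """Fraction of connected neighbor pairs; 0 for degree < 2."""
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    if network.graph.degree(v) < 2:
        return 0.0
    return nx.clustering(network.graph, v)


def closeness(network: ContactNetwork, v: Hashable) -> float:
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    # wf_improved=False gives (r-1)/sum_d within the reachable component
    return nx.closeness_centrality(network.graph, u=v, wf_improved=False)


def betweenness(network: ContactNetwork, v: Hashable) -> float:
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    return betweenness_all(network)[v]


def betweenness_all(network: ContactNetwork) -> dict[Hashable, float]:
    return nx.betweenness_centrality(network.graph, normalized=False)


def coreness(network: ContactNetwork, v: Hashable) -> int:
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    return nx.core_number(network.graph)[v]


def hub_score(network: ContactNetwork, v: Hashable) -> float:
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    return hub_score_all(network)[v]


def hub_score_all(network: ContactNetwork, tol: float = 1e-10,
                  max_iter: int = 1000) -> dict[Hashable, float]:
    """HITS hub scores, rescaled so the maximum over vertices is 1.

    On an undirected graph hubs and authorities coincide and both equal
    the principal (Perron) eigenvector of the adjacency matrix.  Computed
    by power iteration on A + I from a uniform start — the shift leaves
    the eigenvectors unchanged but makes the Perron eigenvalue strictly
    dominant, so the iteration also converges on bipartite graphs, where
    A² is degenerate.  An edgeless graph gets all-zero scores.
    """
    a = network.adjacency_matrix()
    n = len(a)
    if n == 0 or not a.any():
        return {v: 0.0 for v in network.vertices}
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0.0:  # pragma: no cover - excluded by the edge check
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    x /= x.max()
    return dict(zip(network.vertices, x))


def cocitation(network: ContactNetwork, v: Hashable) -> int:
    """Shared-neighbor count summed over all other vertices."""
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    nv = set(network.graph[v])
    return sum(len(nv & set(network.graph[u]))
               for u in network.graph if u != v)


def constraint(network: ContactNetwork, v: Hashable) -> float:
    """Burt constraint with p_uw = 1/degree(u); isolated vertex -> 0."""
    if v not in network.graph:
        raise KeyError(f"unknown vertex {v!r}")
    if network.graph.degree(v) == 0:
        return 0.0
    value = nx.constraint(network.graph, nodes=[v])[v]
    return 0.0 if np.isnan(value) else float(value)


def centrality_table(network: ContactNetwork) -> pd.DataFrame:
    """All eight parameters for every vertex, one row per residue.

    Columns follow :data:`CENTRALITY_NAMES`; the row order matches the
    chain's residue order.
    """
    g = network.graph
    deg = dict(g.degree)
    clust = nx.clustering(g)
    hubs = hub_score_all(network)
    core = nx.core_number(g) if len(g) else {}
    betw = betweenness_all(network)
    a = network.adjacency_matrix()
    a2 = a @ a
    cocit = a2.sum(axis=1) - np.diag(a2)
    rows = []
    for i, v in enumerate(network.vertices):
        rows.append([
            float(deg[v]),
            float(clust[v]) if deg[v] >= 2 else 0.0,
            hubs[v],
            float(cocit[i]),
            float(core[v]),
            constraint(network, v),
            float(betw[v]),
            closeness(network, v),
        ])
    index = pd.Index(network.vertices, tupleize_cols=False)
    return pd.DataFrame(rows, columns=CENTRALITY_NAMES, index=index)
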