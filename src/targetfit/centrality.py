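"""Per-node centrality metrics on simple undirected graphs.

The nine classic node parameters (degree, average shortest path,
eccentricity, neighborhood connectivity, stress, betweenness, closeness,
local clustering coefficient, topological coefficient) plus radiality and
the degree-weighted composite log10(degree x topological coefficient),
following the Cytoscape NetworkAnalyzer conventions:

* path metrics are computed within each connected component; cross-component
  distances are never averaged;
* betweenness and stress count unordered source/target pairs with the node
  strictly interior, betweenness normalised by (n-1)(n-2)/2 per component;
* the topological coefficient of node n is the mean over all partners m
  sharing at least one neighbor with n of J(n, m) / k(n), where J(n, m) is
  the number of shared neighbors plus one if n-m is itself an edge; nodes
  with degree <= 1 or without any sharing partner get 0;
* radiality = (diameter + 1 - average shortest path) / diameter, a strictly
  decreasing transform of the average shortest path (rank statistics on it
  are therefore equivalent to closeness-based ones).
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

#: metrics where a *smaller* value marks a more central node
LOWER_IS_CENTRAL = ("average_shortest_path", "topological_coefficient")

LOCAL_METRICS = (
    "degree",
    "neighborhood_connectivity",
    "clustering_coefficient",
    "topological_coefficient",
)
PATH_METRICS = (
    "average_shortest_path",
    "eccentricity",
    "closeness",
    "radiality",
    "betweenness",
    "stress",
)


def _bfs(adj: dict, source):
    """Return (stack in non-decreasing distance order, predecessors, sigma, dist)."""
    dist = {source: 0}
    sigma = {source: 1}
    pred: dict = {source: []}
    order = [source]
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                pred[w] = []
                order.append(w)
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                pred[w].append(v)
    return order, pred, sigma, dist


def shortest_path_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Geodesic metrics per node, computed per connected component.

    Returns columns average_shortest_path, eccentricity, closeness,
    radiality, betweenness, stress, component, component_diameter.
    Singleton components get NaN path metrics (flagged undefined).
    """
    nodes = list(graph.nodes())
    adj = {n: list(graph.adj[n]) for n in nodes}
    res = {
        name: {}
        for name in (
            "average_shortest_path",
            "eccentricity",
            "closeness",
            "radiality",
            "betweenness",
            "stress",
            "component",
            "component_diameter",
        )
    }
    for ci, comp in enumerate(nx.connected_components(graph)):
        comp = list(comp)
        n = len(comp)
        for v in comp:
            res["component"][v] = ci
        if n == 1:
            v = comp[0]
            for name in ("average_shortest_path", "eccentricity", "closeness", "radiality"):
                res[name][v] = np.nan
            res["betweenness"][v] = 0.0
            res["stress"][v] = 0
            res["component_diameter"][v] = 0
            continue
        bet = dict.fromkeys(comp, 0.0)
        stress = dict.fromkeys(comp, 0.0)
        asp = {}
        ecc = {}
        diameter = 0
        for s in comp:
            order, pred, sigma, dist = _bfs(adj, s)
            asp[s] = (sum(dist.values())) / (n - 1)
            ecc[s] = max(dist.values())
            diameter = max(diameter, ecc[s])
            # Brandes accumulation: delta for betweenness, psi counts the
            # geodesic continuations from each node (stress = sigma * psi).
            delta = dict.fromkeys(order, 0.0)
            psi = dict.fromkeys(order, 0.0)
            for w in reversed(order):
                for v in pred[w]:
                    c = sigma[v] / sigma[w]
                    delta[v] += c * (1.0 + delta[w])
                    psi[v] += 1.0 + psi[w]
                if w != s:
                    bet[w] += delta[w]
                    stress[w] += sigma[w] * psi[w]
        norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
        for v in comp:
            res["average_shortest_path"][v] = asp[v]
            res["eccentricity"][v] = ecc[v]
            res["closeness"][v] = 1.0 / asp[v]
            res["radiality"][v] = (
                (diameter + 1.0 - asp[v]) / diameter if diameter >= 1 else np.nan
            )
            # Brandes sums ordered pairs; halve for unordered.
            res["betweenness"][v] = bet[v] / 2.0 / norm
            res["stress"][v] = int(round(stress[v] / 2.0))
            res["component_diameter"][v] = diameter
    return pd.DataFrame(res, index=pd.Index(nodes, name="node"))


def topological_coefficients(graph: nx.Graph, nodes=None) -> pd.Series:
    """Topological coefficient T(n), optionally restricted to ``nodes``."""
    if nodes is None:
        nodes = list(graph.nodes())
    out = {}
    for n in nodes:
        nbrs = set(graph.adj[n])
        k = len(nbrs)
        if k <= 1:
            out[n] = 0.0
            continue
        shared: dict = {}
        for u in nbrs:
            for m in graph.adj[u]:
                if m != n:
                    shared[m] = shared.get(m, 0) + 1
        if not shared:
            out[n] = 0.0
            continue
        total = sum(j + (1 if m in nbrs else 0) for m, j in shared.items())
        out[n] = total / (len(shared) * k)
    return pd.Series(out, name="topological_coefficient")


def local_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Degree, neighborhood connectivity, clustering and topological coefficient."""
    nodes = list(graph.nodes())
    degree = dict(graph.degree())
    nc = {
        n: (float(np.mean([degree[u] for u in graph.adj[n]])) if degree[n] else 0.0)
        for n in nodes
    }
    clustering = nx.clustering(graph)
    topo = topological_coefficients(graph)
    return pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "neighborhood_connectivity": pd.Series(nc),
            "clustering_coefficient": pd.Series(clustering),
            "topological_coefficient": topo,
        },
        index=pd.Index(nodes, name="node"),
    )


def combined_parameter(table: pd.DataFrame) -> pd.Series:
    """log10(degree * topological coefficient); NaN (excluded) when k=0 or T=0."""
    k = table["degree"].astype(float)
    t = table["topological_coefficient"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log10(k * t)
    values[(k <= 0) | (t <= 0)] = np.nan
    return pd.Series(values, index=table.index, name="log_deg_topo")


def subset_average_shortest_path(graph: nx.Graph, nodes) -> pd.Series:
    """Average shortest path for selected nodes only (one BFS per node)."""
    out = {}
    for n in nodes:
        dist = nx.single_source_shortest_path_length(graph, n)
        out[n] = (sum(dist.values()) / (len(dist) - 1)) if len(dist) > 1 else np.nan
    return pd.Series(out, name="average_shortest_path")


def compute_centrality_table(graph: nx.Graph, include_path_metrics: bool = True) -> pd.DataFrame:
    """Full per-node metric table (the object downstream statistics act on)."""
    table = local_metrics(graph)
    if include_path_metrics:
        table = table.join(shortest_path_metrics(graph))
    table["log_deg_topo"] = combined_parameter(table)
    return table
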