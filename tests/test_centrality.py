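"""Centrality metrics vs hand enumeration and a brute-force oracle."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from targetfit.centrality import (
    combined_parameter,
    compute_centrality_table,
    local_metrics,
    shortest_path_metrics,
    subset_average_shortest_path,
    topological_coefficients,
)
from conftest import random_graph


# ---------------------------------------------------------------------------
# Brute-force oracle: exhaustive geodesic enumeration + direct neighbor-set
# arithmetic on tiny graphs. Independent of the Brandes-style implementation.


def all_geodesics(graph, s, t):
    try:
        length = nx.shortest_path_length(graph, s, t)
    except nx.NetworkXNoPath:
        return []
    return [p for p in nx.all_simple_paths(graph, s, t, cutoff=length) if len(p) - 1 == length]


def oracle_metrics(graph):
    rows = {}
    comps = list(nx.connected_components(graph))
    for comp in comps:
        comp = sorted(comp)
        n = len(comp)
        diameter = 0
        dist = {}
        for s, t in itertools.combinations(comp, 2):
            d = nx.shortest_path_length(graph, s, t)
            dist[(s, t)] = d
            diameter = max(diameter, d)
        for v in comp:
            if n == 1:
                rows[v] = dict(asp=np.nan, ecc=np.nan, close=np.nan, rad=np.nan,
                               bet=0.0, stress=0)
                continue
            dists = [dist[tuple(sorted((v, u)))] for u in comp if u != v]
            asp = float(np.mean(dists))
            bet = 0.0
            stress = 0
            for s, t in itertools.combinations(comp, 2):
                if v in (s, t):
                    continue
                paths = all_geodesics(graph, s, t)
                through = sum(1 for p in paths if v in p[1:-1])
                stress += through
                if paths:
                    bet += through / len(paths)
            norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
            rows[v] = dict(
                asp=asp,
                ecc=max(dists),
                close=1.0 / asp,
                rad=(diameter + 1 - asp) / diameter if diameter >= 1 else np.nan,
                bet=bet / norm,
                stress=stress,
            )
    return rows


def oracle_topological(graph, v):
    nbrs = set(graph[v])
    if len(nbrs) <= 1:
        return 0.0
    js = []
    for m in graph.nodes():
        if m == v:
            continue
        shared = nbrs & set(graph[m])
        if shared:
            js.append(len(shared) + (1 if graph.has_edge(v, m) else 0))
    return float(np.mean(js)) / len(nbrs) if js else 0.0


# ---------------------------------------------------------------------------


class TestHandExamples:
    def test_three_path(self):
        sp = shortest_path_metrics(nx.path_graph(["a", "b", "c"]))
        assert sp.loc["a", "average_shortest_path"] == 1.5
        assert sp.loc["a", "closeness"] == pytest.approx(2 / 3)
        assert sp.loc["a", "eccentricity"] == 2
        assert sp.loc["b", "betweenness"] == 1.0
        assert sp.loc["b", "radiality"] == 1.0

    def test_four_path_stress(self):
        sp = shortest_path_metrics(nx.path_graph(["a", "b", "c", "d"]))
        assert sp.loc["b", "stress"] == 2

    def test_four_cycle_is_vertex_transitive(self):
        sp = shortest_path_metrics(nx.cycle_graph(4))
        assert sp["average_shortest_path"].nunique() == 1
        assert sp.loc[0, "average_shortest_path"] == pytest.approx(4 / 3)
        assert sp["betweenness"].nunique() == 1

    def test_triangle_with_pendant(self, toy_graph):
        lm = local_metrics(toy_graph)
        assert lm.loc["a", "topological_coefficient"] == pytest.approx(5 / 6)
        assert lm.loc["c", "topological_coefficient"] == pytest.approx(2 / 3)
        assert lm.loc["d", "topological_coefficient"] == 0.0
        assert lm.loc["c", "clustering_coefficient"] == pytest.approx(1 / 3)
        assert lm.loc["c", "neighborhood_connectivity"] == pytest.approx(5 / 3)

    def test_complete_graph_topology(self):
        lm = local_metrics(nx.complete_graph(3))
        assert (lm["topological_coefficient"] == 1.0).all()
        assert (lm["clustering_coefficient"] == 1.0).all()

    def test_star_center_has_zero_topological_coefficient(self):
        lm = local_metrics(nx.star_graph(3))
        assert (lm["topological_coefficient"] == 0.0).all()

    def test_combined_parameter_arithmetic(self):
        table = pd.DataFrame(
            {"degree": [10, 1, 100], "topological_coefficient": [0.2, 0.0, 0.01]},
            index=["a", "b", "c"],
        )
        ldt = combined_parameter(table)
        assert ldt["a"] == pytest.approx(np.log10(2))
        assert np.isnan(ldt["b"])
        assert ldt["c"] == pytest.approx(0.0)


class TestOracleEquivalence:
    def test_matches_brute_force_on_200_random_graphs(self, rng):
        """Exhaustive-geodesic oracle agreement on 200 graphs of <= 12 nodes."""
        for _ in range(200):
            g = random_graph(rng)
            sp = shortest_path_metrics(g)
            lm = local_metrics(g)
            expected = oracle_metrics(g)
            for v in g.nodes():
                exp = expected[v]
                if np.isnan(exp["asp"]):
                    assert np.isnan(sp.loc[v, "average_shortest_path"])
                else:
                    assert sp.loc[v, "average_shortest_path"] == pytest.approx(exp["asp"], abs=1e-9)
                    assert sp.loc[v, "closeness"] == pytest.approx(exp["close"], abs=1e-9)
                    assert sp.loc[v, "eccentricity"] == exp["ecc"]
                    if not np.isnan(exp["rad"]):
                        assert sp.loc[v, "radiality"] == pytest.approx(exp["rad"], abs=1e-9)
                assert sp.loc[v, "betweenness"] == pytest.approx(exp["bet"], abs=1e-9)
                assert sp.loc[v, "stress"] == exp["stress"]
                assert lm.loc[v, "topological_coefficient"] == pytest.approx(
                    oracle_topological(g, v), abs=1e-9
                )
                assert lm.loc[v, "degree"] == g.degree(v)

    def test_degree_sum_identity_and_metric_ranges(self, rng):
        for _ in range(20):
            g = random_graph(rng)
            table = compute_centrality_table(g)
            assert table["degree"].sum() == 2 * g.number_of_edges()
            for col, lo, hi in [
                ("betweenness", 0, 1),
                ("clustering_coefficient", 0, 1),
                ("topological_coefficient", 0, 1),
                ("radiality", 0, 1),
                ("closeness", 0, 1),
            ]:
                vals = table[col].dropna()
                assert ((vals >= lo - 1e-12) & (vals <= hi + 1e-12)).all()

    def test_closeness_is_reciprocal_average_path(self, rng):
        g = random_graph(rng)
        sp = shortest_path_metrics(g)
        ok = sp["average_shortest_path"].notna()
        assert np.allclose(
            sp.loc[ok, "closeness"] * sp.loc[ok, "average_shortest_path"], 1.0
        )

    def test_degree_one_nodes_have_zero_topological_coefficient(self, rng):
        for _ in range(20):
            g = random_graph(rng)
            lm = local_metrics(g)
            leaves = lm[lm["degree"] <= 1]
            assert (leaves["topological_coefficient"] == 0.0).all()


class TestSubsetHelpers:
    def test_subset_asp_matches_full_computation(self, rng):
        g = random_graph(rng)
        sp = shortest_path_metrics(g)
        nodes = list(g.nodes())[:5]
        sub = subset_average_shortest_path(g, nodes)
        for v in nodes:
            if np.isnan(sp.loc[v, "average_shortest_path"]):
                continue
            assert sub[v] == pytest.approx(sp.loc[v, "average_shortest_path"])

    def test_subset_topological_matches_full(self, toy_graph):
        full = local_metrics(toy_graph)["topological_coefficient"]
        sub = topological_coefficients(toy_graph, ["a", "d"])
        assert sub["a"] == pytest.approx(full["a"])
        assert sub["d"] == full["d"]
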