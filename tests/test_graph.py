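"""Overlap-net topology: parallel paths, TENPP, diametric path, ranks,
linearity, splitting, Pajek export."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lincontig.graph import (
    OverlapGraph,
    diametric_path,
    export_pajek,
    linearity_check,
    parallel_path_exists,
    split_nonlinear,
    tenpp,
    vertex_ranks,
)


def make_graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        g.add_edge(*e[:2], weight=(e[2] if len(e) > 2 else 20.0))
    return OverlapGraph(nx=g)


def all_simple_paths_oracle(g, u, v, lmin, lmax, forbidden_edge=None, forbidden_vertex=None):
    """Brute-force enumeration of all simple paths of lmin..lmax edges."""
    G = g.nx if isinstance(g, OverlapGraph) else g
    for path in nx.all_simple_paths(G, u, v, cutoff=lmax):
        L = len(path) - 1
        if not (lmin <= L <= lmax):
            continue
        if forbidden_vertex is not None and forbidden_vertex in path[1:-1]:
            continue
        if forbidden_edge is not None:
            fe = tuple(sorted(forbidden_edge))
            if any(tuple(sorted(p)) == fe for p in zip(path, path[1:])):
                continue
        return True
    return False


class TestParallelPaths:
    def test_triangle_edge_has_parallel_path(self):
        g = make_graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert parallel_path_exists(g, ("a", "b"), forbidden_edge=("a", "b"))

    def test_bridge_edge_has_none(self):
        # two triangles joined by a bridge
        g = make_graph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("d", "f")]
        )
        assert not parallel_path_exists(g, ("c", "d"), forbidden_edge=("c", "d"))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        p = float(rng.uniform(0.15, 0.5))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in range(n)})
        g = OverlapGraph(nx=G)
        nodes = sorted(G.nodes)
        u, v = nodes[0], nodes[-1]
        for fe in ([None, (u, v)] if G.has_edge(u, v) else [None]):
            got = parallel_path_exists(g, (u, v), forbidden_edge=fe)
            want = all_simple_paths_oracle(g, u, v, 2, 5, forbidden_edge=fe)
            assert got == want
        if n > 4:
            w = nodes[1]
            got = parallel_path_exists(g, (u, v), forbidden_vertex=w)
            want = all_simple_paths_oracle(g, u, v, 2, 5, forbidden_vertex=w)
            assert got == want


class TestTenpp:
    def test_chain_without_parallels_loses_all_edges(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d")])
        out = tenpp(g)
        assert out.nx.number_of_edges() == 0
        assert len(out.excluded_edges) >= 3

    def test_ladder_graph_fully_proven(self):
        # every edge of a 2x4 ladder lies in a 4-cycle
        G = nx.ladder_graph(4)
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in G.nodes})
        out = tenpp(OverlapGraph(nx=G.copy()))
        assert out.nx.number_of_edges() == G.number_of_edges()
        assert out.excluded_vertices == []

    def test_kept_edges_have_parallel_paths_in_input_graph(self):
        rng = np.random.default_rng(2)
        G = nx.gnp_random_graph(15, 0.3, seed=5)
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in G.nodes})
        g = OverlapGraph(nx=G.copy())
        out = tenpp(g)
        for u, v in out.nx.edges:
            assert all_simple_paths_oracle(g, u, v, 2, 5, forbidden_edge=(u, v))

    def test_exclusions_recorded_not_destroyed(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d")])
        out = tenpp(g)
        excluded = {tuple(sorted(e[:2])) for e in out.excluded_edges}
        assert excluded == {("a", "b"), ("b", "c"), ("c", "d")}

    def test_single_pass_not_fixpoint(self):
        # a 4-cycle with a pendant triangle: the first pass removes some
        # elements; a second pass on the output may remove more, which is
        # exactly why the pass is applied per clustering round
        g = make_graph(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("d", "e"), ("e", "f"), ("f", "d")]
        )
        once = tenpp(g)
        twice = tenpp(once)
        assert once.nx.number_of_edges() >= twice.nx.number_of_edges()


class TestDiametricPath:
    def test_path_graph_returns_itself(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d")])
        assert diametric_path(g) == ["a", "b", "c", "d"]

    def test_cycle_tie_broken_deterministically(self):
        G = nx.cycle_graph(6)
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in G.nodes})
        g = OverlapGraph(nx=G)
        p1 = diametric_path(g)
        p2 = diametric_path(g)
        assert p1 == p2
        assert len(p1) == 4  # diameter 3

    def test_disconnected_graph_raises(self):
        g = make_graph([("a", "b")], nodes=["z"])
        with pytest.raises(ValueError, match="disconnected"):
            diametric_path(g)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_random_tree_length_equals_diameter(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        T = nx.random_labeled_tree(n, seed=int(rng.integers(1 << 30)))
        T = nx.relabel_nodes(T, {i: f"v{i:02d}" for i in T.nodes})
        path = diametric_path(OverlapGraph(nx=T))
        assert len(path) - 1 == nx.diameter(T)


class TestRanksAndLinearity:
    def test_path_vertices_have_rank_zero_pendant_one(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d"), ("b", "x")])
        path = ["a", "b", "c", "d"]
        ranks = vertex_ranks(g, path)
        assert ranks["b"] == 0 and ranks["x"] == 1

    def test_offshoot_rank_matches_apsp_oracle(self):
        rng = np.random.default_rng(8)
        G = nx.connected_watts_strogatz_graph(25, 4, 0.3, seed=4)
        G = nx.relabel_nodes(G, {i: f"v{i:02d}" for i in G.nodes})
        g = OverlapGraph(nx=G)
        path = diametric_path(g)
        ranks = vertex_ranks(g, path)
        apsp = dict(nx.all_pairs_shortest_path_length(G))
        for v in G.nodes:
            assert ranks[v] == min(apsp[v][p] for p in path)

    def test_simple_path_is_linear(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "d")])
        ok, branching = linearity_check(g)
        assert ok and branching == []

    def test_t_shape_flags_junction(self):
        g = make_graph(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("c", "x"), ("x", "y")]
        )
        ok, branching = linearity_check(g)
        assert not ok
        assert "c" in branching

    def test_constructed_y_net_flags_exact_junction(self):
        # three arms of length 3 meeting at vertex "j"
        edges = [("j", "a1"), ("a1", "a2"), ("a2", "a3"),
                 ("j", "b1"), ("b1", "b2"), ("b2", "b3"),
                 ("j", "c1"), ("c1", "c2"), ("c2", "c3")]
        g = make_graph(edges)
        ok, branching = linearity_check(g)
        assert not ok
        assert branching == ["j"]


class TestSplit:
    def test_y_graph_splits_into_linear_arms(self):
        edges = [("j", "a1"), ("a1", "a2"), ("a2", "a3"),
                 ("j", "b1"), ("b1", "b2"), ("b2", "b3"),
                 ("j", "c1"), ("c1", "c2"), ("c2", "c3")]
        parts, removed = split_nonlinear(make_graph(edges))
        assert removed == ["j"]
        assert len(parts) == 3
        for p in parts:
            assert linearity_check(p)[0]

    def test_linear_graph_is_identity(self):
        g = make_graph([("a", "b"), ("b", "c")])
        parts, removed = split_nonlinear(g)
        assert removed == []
        assert len(parts) == 1
        assert sorted(parts[0].nx.nodes) == ["a", "b", "c"]

    def test_all_output_components_linear(self):
        rng = np.random.default_rng(3)
        G = nx.gnp_random_graph(30, 0.12, seed=9)
        G = nx.relabel_nodes(G, {i: f"v{i:02d}" for i in G.nodes})
        parts, _removed = split_nonlinear(OverlapGraph(nx=G))
        for p in parts:
            assert linearity_check(p)[0]


class TestPajek:
    def test_round_trip(self, tmp_path):
        g = make_graph([("cloneA", "cloneB", 15.5), ("cloneB", "cloneC", 30.0)])
        path = tmp_path / "net.net"
        export_pajek(g, path)
        back = nx.read_pajek(path)
        assert set(back.nodes) == {"cloneA", "cloneB", "cloneC"}
        assert back.number_of_edges() == 2

    def test_two_vertex_file_layout(self, tmp_path):
        g = make_graph([("a", "b", 10.0)])
        path = tmp_path / "tiny.net"
        export_pajek(g, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("*Vertices 2")
        assert len(lines) == 5  # header, 2 vertices, *Edges, 1 edge
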